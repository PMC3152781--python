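"""GFF parsing, gene-model cleanup and region extraction."""

import textwrap

import pytest

from tandemscan import (
    GeneModel,
    SequenceRecord,
    dedup_features,
    dedup_gene_models,
    extract_regions,
    infer_intergenic,
    infer_introns,
    infer_utrs,
    parse_gff,
    reverse_complement,
)
from tandemscan.regions import GffParseError


def write_gff(tmp_path, body, name="test.gff3"):
    path = tmp_path / name
    path.write_text("##gff-version 3\n" + textwrap.dedent(body))
    return path


def mk_model(mid="m1", sid="chr1", strand="+", exons=(), cds=(), start=None, stop=None):
    return GeneModel(
        id=mid,
        sequence_id=sid,
        strand=strand,
        exons=list(exons),
        cds_segments=list(cds),
        start_codon=start,
        stop_codon=stop,
    )


class TestParseGff:
    def test_coordinates_convert_to_half_open(self, tmp_path):
        path = write_gff(
            tmp_path,
            """\
            chr1\tsrc\texon\t1\t100\t.\t+\t.\tParent=t1
            """,
        )
        models = parse_gff(path)
        assert models[0].exons == [(0, 100)]

    def test_alternative_transcripts_become_two_models(self, tmp_path):
        path = write_gff(
            tmp_path,
            """\
            chr1\tsrc\texon\t1\t100\t.\t+\t.\tParent=t1
            chr1\tsrc\texon\t201\t300\t.\t+\t.\tParent=t1
            chr1\tsrc\texon\t1\t300\t.\t+\t.\tParent=t2
            """,
        )
        models = parse_gff(path)
        assert sorted(m.id for m in models) == ["t1", "t2"]

    def test_malformed_line_reports_number(self, tmp_path):
        path = tmp_path / "bad.gff"
        path.write_text("chr1\tsrc\texon\t1\t100\t.\t+\n")
        with pytest.raises(GffParseError) as exc:
            parse_gff(path)
        assert exc.value.line == 1

    @pytest.mark.parametrize(
        "line",
        [
            "chr1\tsrc\texon\t100\t1\t.\t+\t.\tID=x",  # end < start
            "chr1\tsrc\texon\t1\t100\t.\t*\t.\tID=x",  # bad strand
        ],
    )
    def test_invalid_coordinates_and_strand(self, tmp_path, line):
        path = tmp_path / "bad.gff"
        path.write_text(line + "\n")
        with pytest.raises(GffParseError):
            parse_gff(path)


class TestDedupGeneModels:
    def test_longer_model_removed(self):
        a = mk_model("long", exons=[(0, 500)])
        b = mk_model("short", exons=[(100, 400)])
        kept = dedup_gene_models([a, b])
        assert [m.id for m in kept] == ["short"]

    def test_opposite_strand_overlap_kept(self):
        a = mk_model("p", strand="+", exons=[(0, 500)])
        b = mk_model("m", strand="-", exons=[(100, 400)])
        assert len(dedup_gene_models([a, b])) == 2

    def test_disjoint_unchanged(self):
        a = mk_model("a", exons=[(0, 100)])
        b = mk_model("b", exons=[(200, 300)])
        assert len(dedup_gene_models([a, b])) == 2

    def test_equal_span_removes_rightmost(self):
        a = mk_model("left", exons=[(0, 100)])
        b = mk_model("right", exons=[(50, 150)])
        kept = dedup_gene_models([a, b])
        assert [m.id for m in kept] == ["left"]

    def test_chain_iterates_until_stable(self):
        ms = [
            mk_model("a", exons=[(0, 1000)]),
            mk_model("b", exons=[(100, 400)]),
            mk_model("c", exons=[(350, 500)]),
        ]
        kept = dedup_gene_models(ms)
        spans = [m.span for m in kept]
        for i, s1 in enumerate(spans):
            for s2 in spans[i + 1 :]:
                assert not (s1[0] < s2[1] and s2[0] < s1[1])


class TestDedupFeatures:
    def test_longer_exon_removed(self):
        m = mk_model(exons=[(0, 300), (100, 200)])
        assert dedup_features(m).exons == [(100, 200)]

    def test_equal_length_keeps_leftmost(self):
        m = mk_model(exons=[(0, 100), (50, 150)])
        assert dedup_features(m).exons == [(0, 100)]

    def test_non_overlapping_unchanged(self):
        m = mk_model(exons=[(0, 100), (200, 300)], cds=[(10, 90)])
        d = dedup_features(m)
        assert d.exons == [(0, 100), (200, 300)] and d.cds_segments == [(10, 90)]


class TestInference:
    def test_introns_are_exon_gaps(self):
        m = mk_model(exons=[(0, 100), (200, 300)])
        assert infer_introns(m) == [(100, 200)]
        assert infer_introns(mk_model(exons=[(0, 100)])) == []
        m3 = mk_model(exons=[(0, 50), (80, 120), (200, 260)])
        assert infer_introns(m3) == [(50, 80), (120, 200)]

    def test_utrs_plus_strand(self):
        m = mk_model(exons=[(0, 300)], start=(100, 103), stop=(297, 300))
        five, three = infer_utrs(m)
        assert five == [(0, 100)] and three == []

    def test_utrs_minus_strand_mirror(self):
        m = mk_model(strand="-", exons=[(0, 300)], start=(197, 200), stop=(0, 3))
        five, three = infer_utrs(m)
        assert five == [(200, 300)]  # upstream in transcription direction
        assert three == []  # stop codon ends at the exon edge

    def test_no_codons_no_utrs(self):
        assert infer_utrs(mk_model(exons=[(0, 300)])) == ([], [])

    def test_codon_outside_exons_flags_model(self):
        m = mk_model(exons=[(0, 100)], start=(150, 153))
        assert infer_utrs(m) == ([], [])
        assert m.flagged

    def test_intergenic_complement(self):
        models = [mk_model(exons=[(100, 200)])]
        assert infer_intergenic({"chr1": 1000}, models) == {
            "chr1": [(0, 100), (200, 1000)]
        }
        assert infer_intergenic({"chr1": 1000}, []) == {"chr1": [(0, 1000)]}
        tiling = [mk_model("a", exons=[(0, 600)]), mk_model("b", exons=[(600, 1000)])]
        assert infer_intergenic({"chr1": 1000}, tiling) == {"chr1": []}


class TestExtractRegions:
    def _genome(self, n=600, seed=4):
        import numpy as np

        rng = np.random.default_rng(seed)
        return [SequenceRecord("chr1", "".join(rng.choice(list("ACGT"), size=n)))]

    def test_minus_strand_cds_is_reverse_complemented(self):
        genome = self._genome()
        m = mk_model(strand="-", exons=[(50, 200)], cds=[(80, 170)])
        frags = extract_regions(genome, [m])
        cds = frags["CDS"][0]
        assert cds.sequence == reverse_complement(genome[0].residues[80:170])
        assert cds.strand == "-"

    def test_plus_strand_intron_unmodified(self):
        genome = self._genome()
        m = mk_model(exons=[(0, 100), (200, 300)])
        frags = extract_regions(genome, [m])
        assert frags["intron"][0].sequence == genome[0].residues[100:200]

    def test_partition_accounting(self):
        genome = self._genome()
        m = mk_model(exons=[(100, 200), (250, 350)])
        frags = extract_regions(genome, [m])
        genic = sum(f.length for k in ("exon", "intron") for f in frags[k])
        intergenic = sum(f.length for f in frags["intergenic"])
        assert genic + intergenic == 600
        span = m.span
        assert genic == span[1] - span[0]

    def test_out_of_bounds_interval_names_model(self):
        genome = self._genome(100)
        m = mk_model("broken", exons=[(50, 200)])
        with pytest.raises(ValueError, match="broken"):
            extract_regions(genome, [m])

    def test_gff_record_order_irrelevant(self, tmp_path):
        body = """\
        chr1\tsrc\texon\t101\t200\t.\t+\t.\tParent=t1
        chr1\tsrc\texon\t301\t400\t.\t+\t.\tParent=t1
        chr1\tsrc\texon\t451\t500\t.\t-\t.\tParent=t2
        """
        shuffled = "\n".join(reversed(textwrap.dedent(body).strip().split("\n"))) + "\n"
        p1 = write_gff(tmp_path, body, "a.gff3")
        p2 = (tmp_path / "b.gff3")
        p2.write_text("##gff-version 3\n" + shuffled)
        genome = self._genome()
        f1 = extract_regions(genome, parse_gff(p1))
        f2 = extract_regions(genome, parse_gff(p2))
        for kind in f1:
            assert sorted((f.start, f.end, f.sequence) for f in f1[kind]) == sorted(
                (f.start, f.end, f.sequence) for f in f2[kind]
            )

    def test_strand_round_trip(self):
        genome = self._genome(300)
        m = mk_model(strand="+", exons=[(40, 120), (180, 260)], cds=[(60, 120), (180, 240)])
        frags = extract_regions(genome, [m])
        n = 300
        rc_genome = [SequenceRecord("chr1", reverse_complement(genome[0].residues))]
        flip = mk_model(
            strand="-",
            exons=[(n - b, n - a) for a, b in reversed(m.exons)],
            cds=[(n - b, n - a) for a, b in reversed(m.cds_segments)],
        )
        rc_frags = extract_regions(rc_genome, [flip])
        for kind in ("CDS", "intron"):
            assert sorted(f.sequence for f in frags[kind]) == sorted(
                f.sequence for f in rc_frags[kind]
            )
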