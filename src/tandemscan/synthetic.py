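"""Synthetic genomes with planted tandem repeats of known truth.

The generator emulates the inputs the scanner is built for: genome
fragments of realistic base composition containing tandem repeats of
known location, unit, score and perfection, plus GFF gene models so the
region pipeline (CDS/intron/UTR/intergenic, sense strands) can be
exercised end to end without downloads.

Plants are written as perfect arrays first; requested substitutions,
indels and N runs are then applied at seeded positions outside the
first unit, spaced so that every edit is recovered by the detector's
improving-segment extension (at least six intact columns after each
edit and before the array end, and a full unit plus four bases of
perfect sequence at the array start so a seed always exists).  Under
those constraints the expected score of a plant follows directly from
the column ledger: a perfect plant of length L and unit size p scores
L - p; each substitution or deletion costs 6, each insertion 5, and
each N column 1.

Backgrounds are i.i.d. bases at a requested GC content and can be
rejection-sampled until they contain no qualifying repeat (verified
with the detector).  Whole fixtures can likewise be verified so that
every plant is recovered exactly; padding of at least 25 bp keeps
plants from merging.  Identical config and seed give byte-identical
output.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .detect import find_repeats
from .regions import GeneModel, extract_regions
from .scoring import ScoringScheme
from .seq_io import SequenceRecord, write_fasta
from .units import reverse_complement

PAD = 25  # minimum non-repetitive padding around every plant, bp
_EDIT_TAIL = 6  # intact columns required after each edit and before the end


@dataclass(frozen=True)
class PlantSpec:
    """One repeat to plant: unit, copy number and imperfections."""

    unit: str
    copies: float
    n_mismatch: int = 0
    n_insert: int = 0
    n_delete: int = 0
    n_nrun: int = 0
    nrun_length: int = 2
    position: int | None = None  # genome offset, or None for random
    strand: str = "+"

    def __post_init__(self):
        if self.copies < 2:
            raise ValueError("a tandem repeat needs at least two unit copies")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if self.nrun_length < 1:
            raise ValueError("nrun_length must be >= 1")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one plant, in genome coordinates."""

    sequence_id: str
    start: int
    end: int
    unit: str  # as read on the forward genomic strand, phase at start
    unit_size: int
    expected_score: int
    expected_perfection: float
    region_kind: str = "unplaced"
    sense_unit: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start


class PlantError(ValueError):
    pass


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def random_background(
    length: int,
    gc: float = 0.5,
    seed=0,
    ensure_repeat_free: bool = False,
    scheme: ScoringScheme | None = None,
    max_tries: int = 30,
    seq_id: str = "background",
) -> SequenceRecord:
    """I.i.d. background at the requested GC content.

    With ``ensure_repeat_free`` the draw is repeated until the detector
    finds nothing; if ``max_tries`` draws all fail, the last draw is
    returned with a warning (composition extremes such as gc=1 can make
    repeat-free sequence impossible).
    """
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0 <= gc <= 1:
        raise ValueError("gc must lie in [0, 1]")
    rng = _rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = np.array(list("ACGT"))
    if scheme is None:
        scheme = ScoringScheme()
    for _ in range(max_tries):
        s = "".join(rng.choice(bases, size=length, p=probs))
        rec = SequenceRecord(seq_id, s)
        if not ensure_repeat_free or not find_repeats(rec, scheme):
            return rec
    warnings.warn(
        f"no repeat-free background of length {length} found in {max_tries} tries; "
        "returning the last draw",
        stacklevel=2,
    )
    return rec


def build_plant(spec: PlantSpec, seed=0, scheme: ScoringScheme | None = None):
    """Construct the plant string and its exact expected statistics.

    Returns (plant_string, expected_score, expected_perfection).
    Raises PlantError when the requested edits cannot be placed without
    breaking recoverability or the qualifying score.
    """
    if scheme is None:
        scheme = ScoringScheme()
    rng = _rng(seed)
    u = spec.unit.upper()
    p = len(u)
    L = int(round(spec.copies * p))
    perfect = (u * (L // p + 1))[:L]

    # eligible edit anchor positions: outside the first unit and the
    # seed head, clear of the tail, spaced so each edit's following run
    # still improves the score
    n_point = spec.n_mismatch + spec.n_insert + spec.n_delete + spec.n_nrun
    head = max(p + 4, p + 1)
    lo, hi = head, L - _EDIT_TAIL
    slot_w = _EDIT_TAIL + 1 + (spec.nrun_length if spec.n_nrun else 0)
    if n_point:
        if hi <= lo or (hi - lo) < n_point * slot_w:
            raise PlantError(
                f"plant of {L} bp (unit {u}) has no room for {n_point} edits"
            )
        anchors = sorted(
            rng.choice(np.arange(lo, hi - slot_w + 1), size=n_point, replace=False)
        )
        # enforce spacing; bail out rather than silently clustering
        for a, b in zip(anchors, anchors[1:]):
            if b - a < slot_w:
                raise PlantError(
                    "edit positions collide; request fewer edits or more copies"
                )
    else:
        anchors = []

    ops = (
        ["X"] * spec.n_mismatch
        + ["I"] * spec.n_insert
        + ["D"] * spec.n_delete
        + ["R"] * spec.n_nrun
    )
    rng.shuffle(ops)

    chars = list(perfect)
    n_match = L
    n_mm = n_ins = n_del = n_ncol = 0
    # apply right-to-left so earlier anchor coordinates stay valid
    for anchor, op in sorted(zip(anchors, ops), reverse=True):
        ref = perfect[anchor]
        if op == "X":
            alt = rng.choice([c for c in "ACGT" if c != ref])
            chars[anchor] = alt
            n_match -= 1
            n_mm += 1
        elif op == "I":
            alt = rng.choice([c for c in "ACGT" if c != ref])
            chars.insert(anchor, alt)
            n_ins += 1
        elif op == "D":
            del chars[anchor]
            n_match -= 1
            n_del += 1
        else:  # N run
            k = spec.nrun_length
            if k > scheme.max_successive_ns:
                raise PlantError(
                    f"N runs of {k} exceed the detector's cap of "
                    f"{scheme.max_successive_ns} and would split the plant"
                )
            chars[anchor : anchor + k] = ["N"] * k
            n_match -= k
            n_ncol += k

    ms, xs, gs = scheme.match_score, scheme.mismatch_score, scheme.gap_score
    score = n_match * ms + n_mm * xs + (n_ins + n_del) * gs + n_ncol * scheme.n_score
    score -= p * ms
    if score < scheme.min_score(p):
        raise PlantError(
            f"plant would score {score}, below the qualifying "
            f"{scheme.min_score(p)} for unit size {p}"
        )
    columns = n_match + n_mm + n_ins + n_del + n_ncol
    perfection = 100.0 * n_match / columns
    return "".join(chars), score, perfection


def plant(
    seq: SequenceRecord,
    spec: PlantSpec,
    seed=0,
    scheme: ScoringScheme | None = None,
) -> tuple[SequenceRecord, TruthRecord]:
    """Write one plant into a background sequence (slice replacement)."""
    rng = _rng(seed)
    body, score, perfection = build_plant(spec, rng, scheme)
    if spec.strand == "-":
        genomic = reverse_complement(body)
    else:
        genomic = body
    n = len(seq.residues)
    L = len(genomic)
    if spec.position is not None:
        pos = spec.position
    else:
        if n < L + 2 * PAD:
            raise PlantError(f"background of {n} bp too small for a {L} bp plant")
        pos = int(rng.integers(PAD, n - L - PAD + 1))
    if pos < 0 or pos + L > n:
        raise PlantError(f"plant at {pos} (length {L}) exceeds the sequence")
    residues = seq.residues[:pos] + genomic + seq.residues[pos + L :]
    p = len(spec.unit)
    # guard bases: break the unit period immediately left and right of
    # the plant so chance continuation of the tiling cannot shift the
    # truth interval
    chars = list(residues)
    if pos > 0:
        blocked = {genomic[p - 1], "N"}
        chars[pos - 1] = str(rng.choice([c for c in "ACGT" if c not in blocked]))
    if pos + L < n:
        blocked = {genomic[L - p], "N"}
        chars[pos + L] = str(rng.choice([c for c in "ACGT" if c not in blocked]))
    residues = "".join(chars)
    unit_fwd = genomic[: len(spec.unit)]
    truth = TruthRecord(
        sequence_id=seq.id,
        start=pos,
        end=pos + L,
        unit=unit_fwd,
        unit_size=len(spec.unit),
        expected_score=score,
        expected_perfection=perfection,
        sense_unit=spec.unit.upper(),
    )
    return SequenceRecord(seq.id, residues), truth


# ---------------------------------------------------------------------------
# whole-genome fixtures with gene models


@dataclass(frozen=True)
class GeneLayout:
    """Sizes of the synthetic three-exon gene template, in bp."""

    exon_sizes: tuple[int, ...] = (400, 500, 400)
    intron_sizes: tuple[int, ...] = (500, 500)
    utr5: int = 100
    utr3: int = 120

    @property
    def span(self) -> int:
        return sum(self.exon_sizes) + sum(self.intron_sizes)


@dataclass(frozen=True)
class RegionPlant:
    """A plant requested inside a particular region kind.

    ``strand='+'`` means the unit reads as given on the *sense* strand
    of the enclosing gene (for stranded kinds) or on the forward strand
    (intergenic)."""

    kind: str
    spec: PlantSpec


@dataclass(frozen=True)
class FixtureConfig:
    n_sequences: int = 1
    sequence_length: int = 30_000
    gc: float = 0.40
    genes_per_sequence: int = 4
    layout: GeneLayout = GeneLayout()
    plants: tuple[RegionPlant, ...] = ()
    verify: bool = True  # regenerate until every plant is recovered exactly
    max_tries: int = 20


def default_fixture_config() -> FixtureConfig:
    """The stock fixture: repeats of several classes in every region kind,
    with a deliberate AAG sense-strand bias in CDS for strandedness."""
    return FixtureConfig(
        plants=(
            RegionPlant("CDS", PlantSpec(unit="AAG", copies=10)),
            RegionPlant("CDS", PlantSpec(unit="AAG", copies=8)),
            RegionPlant("CDS", PlantSpec(unit="AGC", copies=9)),
            RegionPlant("intron", PlantSpec(unit="A", copies=20)),
            RegionPlant("intron", PlantSpec(unit="AT", copies=9)),
            RegionPlant("intron", PlantSpec(unit="AC", copies=12, n_mismatch=1)),
            RegionPlant("five_prime_UTR", PlantSpec(unit="AG", copies=8)),
            RegionPlant("three_prime_UTR", PlantSpec(unit="AAT", copies=7)),
            RegionPlant("intergenic", PlantSpec(unit="AAG", copies=10)),
            RegionPlant("intergenic", PlantSpec(unit="CTT", copies=10)),
            RegionPlant(
                "intergenic", PlantSpec(unit="AAAAGTTCAACTTTATG", copies=6)
            ),
            RegionPlant("intergenic", PlantSpec(unit="ACGTT", copies=8, n_nrun=1)),
        ),
    )


def _layout_models(config: FixtureConfig, seq_id: str, seq_len: int) -> list[GeneModel]:
    lay = config.layout
    span = lay.span
    g = config.genes_per_sequence
    if g == 0:
        return []
    gap = (seq_len - g * span) // (g + 1)
    if gap < 2 * PAD:
        raise ValueError("sequence too short for the requested gene count")
    models = []
    offset = gap
    for k in range(g):
        strand = "+" if k % 2 == 0 else "-"
        exons = []
        pos = offset
        for es, is_ in zip(lay.exon_sizes, lay.intron_sizes + (0,)):
            exons.append((pos, pos + es))
            pos += es + is_
        if strand == "+":
            start_codon = (exons[0][0] + lay.utr5, exons[0][0] + lay.utr5 + 3)
            stop_codon = (exons[-1][1] - lay.utr3 - 3, exons[-1][1] - lay.utr3)
        else:
            start_codon = (exons[-1][1] - lay.utr5 - 3, exons[-1][1] - lay.utr5)
            stop_codon = (exons[0][0] + lay.utr3, exons[0][0] + lay.utr3 + 3)
        # CDS: exonic sequence between the codons (inclusive of both)
        if strand == "+":
            c0, c1 = start_codon[0], stop_codon[1]
        else:
            c0, c1 = stop_codon[0], start_codon[1]
        cds = [
            (max(a, c0), min(b, c1)) for a, b in exons if max(a, c0) < min(b, c1)
        ]
        models.append(
            GeneModel(
                id=f"{seq_id}.g{k + 1}",
                sequence_id=seq_id,
                strand=strand,
                exons=exons,
                cds_segments=cds,
                start_codon=start_codon,
                stop_codon=stop_codon,
            )
        )
        offset += span + gap
    return models


def _placement_intervals(models, seq_len, kind):
    """Genomic intervals of one region kind available for planting."""
    dummy = [SequenceRecord(models[0].sequence_id if models else "s", "A" * seq_len)]
    frags = extract_regions(dummy, models) if models else {k: [] for k in ("CDS",)}
    if kind == "intergenic" and not models:
        return [(0, seq_len, ".")]
    out = []
    for f in frags.get(kind, []):
        out.append((f.start, f.end, f.strand))
    return out


def models_to_gff3(models: list[GeneModel]) -> str:
    """Serialize gene models as GFF3 (gene/mRNA/exon/CDS/codon lines)."""
    lines = ["##gff-version 3"]
    for m in models:
        a, b = m.span
        gene_id = m.id + ".gene"
        lines.append(
            f"{m.sequence_id}\ttandemscan\tgene\t{a + 1}\t{b}\t.\t{m.strand}\t.\tID={gene_id}"
        )
        lines.append(
            f"{m.sequence_id}\ttandemscan\tmRNA\t{a + 1}\t{b}\t.\t{m.strand}\t.\t"
            f"ID={m.id};Parent={gene_id}"
        )
        for x, y in m.exons:
            lines.append(
                f"{m.sequence_id}\ttandemscan\texon\t{x + 1}\t{y}\t.\t{m.strand}\t.\tParent={m.id}"
            )
        for x, y in m.cds_segments:
            lines.append(
                f"{m.sequence_id}\ttandemscan\tCDS\t{x + 1}\t{y}\t.\t{m.strand}\t0\tParent={m.id}"
            )
        for name, iv in (("start_codon", m.start_codon), ("stop_codon", m.stop_codon)):
            if iv is not None:
                lines.append(
                    f"{m.sequence_id}\ttandemscan\t{name}\t{iv[0] + 1}\t{iv[1]}\t.\t"
                    f"{m.strand}\t0\tParent={m.id}"
                )
    return "\n".join(lines) + "\n"


@dataclass
class FixtureBundle:
    """A generated genome: sequences, gene models and the truth table."""

    sequences: list[SequenceRecord]
    models: list[GeneModel]
    truth: list[TruthRecord]
    config: FixtureConfig
    seed: int

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sequence_id": t.sequence_id,
                    "start": t.start,
                    "end": t.end,
                    "unit": t.unit,
                    "unit_size": t.unit_size,
                    "expected_score": t.expected_score,
                    "expected_perfection": t.expected_perfection,
                    "region_kind": t.region_kind,
                    "sense_unit": t.sense_unit,
                }
                for t in self.truth
            ]
        )

    def gff3(self) -> str:
        return models_to_gff3(self.models)

    def fasta(self) -> str:
        buf = io.StringIO()
        write_fasta(self.sequences, buf)
        return buf.getvalue()

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "genome.fa",
            "gff": outdir / "genome.gff3",
            "truth": outdir / "truth.tsv",
        }
        paths["fasta"].write_text(self.fasta())
        paths["gff"].write_text(self.gff3())
        self.truth_frame().to_csv(paths["truth"], sep="\t", index=False)
        return paths


def _try_build(config: FixtureConfig, rng: np.random.Generator, scheme: ScoringScheme):
    sequences = []
    truth: list[TruthRecord] = []
    all_models: list[GeneModel] = []
    for si in range(config.n_sequences):
        seq_id = f"syn{si + 1}"
        rec = random_background(
            config.sequence_length, config.gc, rng, seq_id=seq_id
        )
        models = _layout_models(config, seq_id, config.sequence_length)
        all_models.extend(models)
        occupied: list[tuple[int, int]] = []
        for rp in config.plants:
            intervals = _placement_intervals(models, config.sequence_length, rp.kind)
            body_len = (int(round(rp.spec.copies * len(rp.spec.unit))) + rp.spec.n_insert - rp.spec.n_delete)
            placed = False
            order = rng.permutation(len(intervals))
            for idx in order:
                a, b, strand = intervals[int(idx)]
                room = (b - a) - body_len - 2 * PAD
                if room < 0:
                    continue
                pos = a + PAD + int(rng.integers(0, room + 1))
                iv = (pos - PAD, pos + body_len + PAD)
                if any(x0 < iv[1] and iv[0] < x1 for x0, x1 in occupied):
                    continue
                genome_strand = "+"
                if rp.kind != "intergenic" and strand == "-":
                    genome_strand = "-"  # sense unit must appear reverse
                spec = replace(rp.spec, position=pos, strand=genome_strand)
                rec, t = plant(rec, spec, rng, scheme)
                t = replace(t, region_kind=rp.kind)
                truth.append(t)
                occupied.append(iv)
                placed = True
                break
            if not placed:
                raise PlantError(
                    f"no room for a {body_len} bp plant in region kind {rp.kind}"
                )
        sequences.append(rec)
    truth.sort(key=lambda t: (t.sequence_id, t.start))
    return sequences, all_models, truth


def _recovered_exactly(bundle_seqs, truth, scheme) -> bool:
    by_seq: dict[str, list[TruthRecord]] = {}
    for t in truth:
        by_seq.setdefault(t.sequence_id, []).append(t)
    for rec in bundle_seqs:
        hits = find_repeats(rec, scheme)
        want = {
            (t.start, t.end, t.unit_size, t.expected_score)
            for t in by_seq.get(rec.id, [])
        }
        got = {(h.start, h.end, h.unit_size, h.score) for h in hits}
        if want != got:
            return False
    return True


def make_fixture_genome(
    config: FixtureConfig | None = None,
    seed: int = 0,
    scheme: ScoringScheme | None = None,
) -> FixtureBundle:
    """Generate a genome fixture: FASTA-able sequences, GFF gene models
    and a truth table, deterministically from (config, seed).

    With ``config.verify`` the whole fixture is re-drawn (bounded by
    ``max_tries``) until the detector recovers every plant exactly, so
    chance repeats in the background can never blur the truth.
    """
    if config is None:
        config = default_fixture_config()
    if scheme is None:
        scheme = ScoringScheme()
    tries = config.max_tries if config.verify else 1
    last_exc: Exception | None = None
    for t in range(tries):
        rng = np.random.default_rng((seed, t))
        try:
            sequences, models, truth = _try_build(config, rng, scheme)
        except PlantError as exc:
            last_exc = exc
            continue
        if not config.verify or _recovered_exactly(sequences, truth, scheme):
            return FixtureBundle(sequences, models, truth, config, seed)
    if last_exc is not None:
        raise last_exc
    raise PlantError(
        f"could not build a verified fixture in {tries} tries; "
        "the config likely leaves plants too little padding"
    )
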