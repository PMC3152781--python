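"""Detector behaviour: scoring, thresholds, extension, overlap resolution."""

import numpy as np
import pytest

from tandemscan import (
    RepeatHit,
    ScoringScheme,
    SequenceRecord,
    alternative_unit_analysis,
    extend_candidate,
    find_repeats,
    resolve_overlaps,
    reverse_complement,
    score_alignment,
)


def one_hit(s, scheme=None):
    hits = find_repeats(SequenceRecord("t", s), scheme)
    assert len(hits) == 1, f"expected one hit, got {hits}"
    return hits[0]


class TestScoreAlignment:
    def test_perfect_mono_13(self):
        assert score_alignment("M" * 13, 1) == 12

    def test_perfect_di_14(self):
        assert score_alignment("M" * 14, 2) == 12

    def test_one_substitution(self):
        # 14 bp poly-A with one substitution: 12 scored matches, one -5
        assert score_alignment("M" * 13 + "X", 1) == 7

    def test_n_columns_score_zero(self):
        assert score_alignment("M" * 10 + "NNNN" + "M" * 10, 2) == 18

    def test_rejects_unknown_opcode(self):
        with pytest.raises(ValueError):
            score_alignment("MZZ", 1)


class TestThresholdEmergence:
    """The published minimum lengths arise from the scoring rules alone."""

    @pytest.mark.parametrize("p,min_len", [(1, 13), (2, 14), (3, 15)])
    def test_smallest_qualifying_perfect_repeat(self, p, min_len):
        unit = "ACG"[:p] if p < 3 else "ACG"
        for L in range(2 * p, min_len):
            assert find_repeats(SequenceRecord("t", (unit * L)[:L])) == []
        hit = one_hit((unit * min_len)[:min_len])
        assert (hit.length, hit.score, hit.unit_size) == (min_len, 12, p)

    @pytest.mark.parametrize("p", [13, 20, 37])
    def test_two_units_needed_above_12(self, p):
        rng = np.random.default_rng(p)
        unit = "".join(rng.choice(list("ACGT"), size=p))
        while len(set(unit)) < 3:  # avoid accidentally periodic units
            unit = "".join(rng.choice(list("ACGT"), size=p))
        scheme = ScoringScheme(unit_min=1, unit_max=60)
        short = (unit * 2)[: 2 * p - 1]
        full = unit * 2
        assert find_repeats(SequenceRecord("t", short), scheme) == []
        hits = find_repeats(SequenceRecord("t", full), scheme)
        primary = [h for h in hits if h.unit_size == p]
        assert primary and primary[0].score == p and primary[0].length == 2 * p


class TestFindRepeats:
    def test_poly_a_12_not_reported(self):
        assert find_repeats(SequenceRecord("t", "A" * 12)) == []

    def test_poly_a_13(self):
        h = one_hit("A" * 13)
        assert (h.unit, h.length, h.score, h.perfection) == ("A", 13, 12, 100.0)

    def test_hexamer_with_flanks(self):
        h = one_hit("GGTCG" + "ACACAT" * 4 + "GTTGC")
        assert (h.start, h.end) == (5, 29)
        assert (h.unit, h.unit_size, h.score) == ("ACACAT", 6, 18)
        assert (2, -2) in h.alternatives

    def test_four_ns_bridged(self):
        h = one_hit("AC" * 10 + "NNNN" + "AC" * 10)
        assert (h.start, h.end, h.score) == (0, 44, 38)
        assert h.n_ncol == 4

    def test_five_ns_never_bridged(self):
        hits = find_repeats(SequenceRecord("t", "AC" * 10 + "NNNNN" + "AC" * 10))
        assert [(h.start, h.end, h.score) for h in hits] == [
            (0, 20, 18),
            (25, 45, 18),
        ]

    def test_imperfect_repeat_extension(self):
        # (AC)x7, one substitution, (AC)x7: bridge costs 6, regains 14
        s = "AC" * 7 + "G" + "C" + "AC" * 6
        h = one_hit(s)
        assert h.start == 0 and h.end == len(s)
        assert h.score == 14 + 14 - 2 - 5 - 1  # 26 matches scored, one mismatch
        assert h.n_mismatch == 1

    def test_no_hit_contains_long_n_runs(self):
        rng = np.random.default_rng(5)
        s = "".join(rng.choice(list("ACGTN"), size=400, p=[0.22, 0.22, 0.22, 0.22, 0.12]))
        for h in find_repeats(SequenceRecord("t", s), ScoringScheme(unit_min=1, unit_max=6)):
            frag = s[h.start : h.end]
            assert "N" * 5 not in frag

    def test_determinism(self):
        rng = np.random.default_rng(42)
        s = "".join(rng.choice(list("ACGT"), size=600))
        s = s[:200] + "TTAGGC" * 6 + s[200:]
        rec = SequenceRecord("t", s)
        a = find_repeats(rec)
        b = find_repeats(rec)
        assert a == b

    def test_strand_complementarity(self):
        rng = np.random.default_rng(9)
        for trial in range(10):
            s = "".join(rng.choice(list("ACGT"), size=250))
            unit = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 6))))
            pos = int(rng.integers(20, 150))
            s = s[:pos] + unit * 14 + s[pos:]
            rec = SequenceRecord("t", s)
            rc = SequenceRecord("t", reverse_complement(s))
            fwd = find_repeats(rec, ScoringScheme(unit_min=1, unit_max=6))
            rev = find_repeats(rc, ScoringScheme(unit_min=1, unit_max=6))
            n = len(s)
            mirrored = sorted(
                (n - h.end, n - h.start, h.unit_size, h.score) for h in rev
            )
            assert mirrored == [(h.start, h.end, h.unit_size, h.score) for h in fwd]


def test_long_preset_finds_minisatellite_units():
    """The 1-4000 bp preset (score reduction 30) detects a 150 bp unit
    repeated three times, with score 2L/3 = length minus one unit."""
    rng = np.random.default_rng(31)
    unit = "".join(rng.choice(list("ACGT"), size=150))
    flank = "".join(rng.choice(list("ACGT"), size=600))
    s = flank + unit * 3 + flank[::-1]
    hits = find_repeats(SequenceRecord("t", s), ScoringScheme.long_preset())
    big = [h for h in hits if h.unit_size == 150]
    assert len(big) == 1
    assert big[0].score >= 300  # 450 columns minus one unscored unit


class TestExtendCandidate:
    def test_flanks_only_lower_the_score(self):
        s = "GGG" + "AC" * 7 + "GGG"
        hit = extend_candidate(SequenceRecord("t", s), 3, 17, "AC")
        assert (hit.start, hit.end, hit.score) == (3, 17, 12)

    def test_returns_none_below_min_score(self):
        s = "GGG" + "AC" * 5 + "GGG"
        assert extend_candidate(SequenceRecord("t", s), 3, 13, "AC") is None

    def test_rejects_bad_seed(self):
        with pytest.raises(ValueError):
            extend_candidate(SequenceRecord("t", "ACGTACGT"), 0, 8, "AC")


class TestAlternativeUnits:
    def test_hexamer_vs_dimer(self, scheme):
        h = one_hit("ACACAT" * 4)
        alts = alternative_unit_analysis(h, SequenceRecord("t", "ACACAT" * 4), scheme)
        assert alts == [(6, 18), (2, -2)]

    def test_perfect_dimer_reports_no_periodic_multiples(self, scheme):
        h = one_hit("AC" * 10)
        alts = alternative_unit_analysis(h, SequenceRecord("t", "AC" * 10), scheme)
        assert alts == [(2, 18)]  # ACAC is periodic, never a separate reading

    def test_homopolymer_has_single_interpretation(self, scheme):
        h = one_hit("A" * 13)
        assert alternative_unit_analysis(h, SequenceRecord("t", "A" * 13), scheme) == [
            (1, 12)
        ]


def _mkhit(start, end, unit, score):
    return RepeatHit(
        sequence_id="s",
        start=start,
        end=end,
        unit=unit,
        unit_size=len(unit),
        score=score,
        n_match=end - start,
        n_mismatch=0,
        n_gap=0,
        n_ncol=0,
    )


class TestResolveOverlaps:
    def test_same_interval_higher_score_wins(self):
        a = _mkhit(0, 24, "ACACAT", 18)
        b = _mkhit(0, 24, "AC", -2)
        out = resolve_overlaps([a, b])
        assert len(out) == 1 and out[0].unit_size == 6
        assert (2, -2) in out[0].alternatives

    def test_disjoint_unchanged(self):
        a = _mkhit(0, 20, "AC", 18)
        b = _mkhit(30, 43, "A", 12)
        assert [(h.start, h.end) for h in resolve_overlaps([a, b])] == [
            (0, 20),
            (30, 43),
        ]

    def test_equal_score_smaller_unit_wins(self):
        a = _mkhit(0, 20, "ACAG", 14)
        b = _mkhit(2, 22, "AC", 14)
        out = resolve_overlaps([a, b])
        assert len(out) == 1 and out[0].unit_size == 2

    def test_equal_everything_leftmost_wins(self):
        a = _mkhit(5, 25, "AG", 14)
        b = _mkhit(0, 20, "AG", 14)
        out = resolve_overlaps([a, b])
        assert len(out) == 1 and out[0].start == 0


class TestSchemeValidation:
    def test_default_matches_published_configuration(self, scheme):
        assert (
            scheme.match_score,
            scheme.mismatch_score,
            scheme.gap_score,
            scheme.n_score,
        ) == (1, -5, -5, 0)
        assert scheme.min_score(1) == 12
        assert scheme.min_score(12) == 12
        assert scheme.min_score(13) == 13
        assert scheme.max_successive_ns == 4
        assert scheme.recursion_depth == 5
        assert ScoringScheme.short_preset().max_score_reduction is None
        assert ScoringScheme.long_preset().max_score_reduction == 30

    def test_invalid_schemes_rejected(self):
        with pytest.raises(ValueError):
            ScoringScheme(match_score=0)
        with pytest.raises(ValueError):
            ScoringScheme(mismatch_score=1)
        with pytest.raises(ValueError):
            ScoringScheme(unit_min=5, unit_max=2)
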