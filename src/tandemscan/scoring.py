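"""Alignment scoring scheme for tandem-repeat detection.

A repeat region is scored by aligning it to a perfect tandem tiling of
its unit.  Columns score match +1, mismatch -5, gap -5 and N 0 by
default, and one perfect unit's worth of match score is subtracted so
that "the first repeat unit" never counts: a perfect repeat of total
length L with unit size p scores L - p.

A hit qualifies when its score reaches 12 for unit sizes up to 12 bp,
or the unit size itself for longer units.  Consequently the shortest
qualifying perfect mono-, di- and trinucleotide repeats are 13, 14 and
15 bp long, and a perfect repeat with unit size > 12 bp must span at
least two units.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional


@dataclass(frozen=True)
class ScoringScheme:
    """All detection parameters.

    ``max_score_reduction=None`` means unlimited: an extension branch is
    never abandoned for having dipped below the best score seen on its
    side.  The two presets mirror the two unit-size ranges the scheme is
    normally run with: 1-50 bp with unlimited reduction, and 1-4000 bp
    with a reduction cap of 30 to bound the search.
    """

    match_score: int = 1
    mismatch_score: int = -5
    gap_score: int = -5
    n_score: int = 0
    min_score_floor: int = 12
    max_successive_ns: int = 4
    recursion_depth: int = 5
    max_score_reduction: Optional[int] = None
    unit_min: int = 1
    unit_max: int = 50

    def __post_init__(self):
        if self.match_score <= 0:
            raise ValueError("match_score must be positive")
        if self.mismatch_score >= 0 or self.gap_score >= 0:
            raise ValueError("mismatch_score and gap_score must be negative")
        if not 0 <= self.n_score <= self.match_score:
            raise ValueError("n_score must lie in [0, match_score]")
        if self.unit_min < 1 or self.unit_max < self.unit_min:
            raise ValueError("need 1 <= unit_min <= unit_max")

    def min_score(self, unit_size: int) -> int:
        """Qualifying score: the floor for short units, else the unit size."""
        if unit_size <= self.min_score_floor:
            return self.min_score_floor
        return unit_size

    def with_unit_range(self, unit_min: int, unit_max: int) -> "ScoringScheme":
        return replace(self, unit_min=unit_min, unit_max=unit_max)

    @classmethod
    def short_preset(cls) -> "ScoringScheme":
        """Unit sizes 1-50 bp, unlimited score reduction."""
        return cls(unit_min=1, unit_max=50, max_score_reduction=None)

    @classmethod
    def long_preset(cls) -> "ScoringScheme":
        """Unit sizes 1-4000 bp, score reduction capped at 30."""
        return cls(unit_min=1, unit_max=4000, max_score_reduction=30)
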