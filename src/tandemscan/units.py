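"""Canonical forms of tandem-repeat units.

A repeat unit can be read in any phase (cyclic rotation) and on either
strand (reverse complement).  Two canonical forms are used throughout:

* the *repeat type* — canonical under rotation **and** reverse
  complement, so AAG, AGA, GAA, TTC, TCT and CTT all map to AAG.  Types
  identify a repeat irrespective of phase and strand.
* the *repeat motif* — canonical under rotation only, so AAG/AGA/GAA map
  to AAG while TTC/TCT/CTT map to CTT.  Motifs keep strand information
  and are the unit of strandedness analysis.

The *repeat class* of a unit is simply its length in bp.

Canonical means "first in plain lexicographic (ASCII) order", i.e.
A < C < G < N < T.  Units that are themselves periodic (ACAC) are
reduced to their primitive period (AC) before canonicalization so the
same repeat is never classified under two unit sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_ALPHABET = frozenset("ACGTN")


def _check_unit(u: str) -> None:
    if not u:
        raise ValueError("repeat unit must be non-empty")
    if not _ALPHABET.issuperset(u):
        bad = sorted(set(u) - _ALPHABET)
        raise ValueError(f"repeat unit contains invalid symbols: {bad}")


def reverse_complement(u: str) -> str:
    """Reverse-complemented unit; N is self-complementary."""
    _check_unit(u)
    return u.translate(_COMPLEMENT)[::-1]


def rotations(u: str) -> list[str]:
    """All cyclic rotations of ``u`` (including ``u`` itself)."""
    return [u[i:] + u[:i] for i in range(len(u))]


def primitive_unit(u: str) -> str:
    """Reduce a periodic unit to its primitive period.

    ``ACAC`` -> ``AC``; ``AAA`` -> ``A``; a primitive unit is returned
    unchanged.  Uses the classic doubling trick: u is periodic with
    period d | len(u) iff u occurs in (u+u) at offset d < len(u).
    """
    _check_unit(u)
    n = len(u)
    d = (u + u).find(u, 1)
    return u[:d] if d < n else u


def is_primitive(u: str) -> bool:
    return primitive_unit(u) == u


@lru_cache(maxsize=65536)
def canonical_motif(u: str) -> str:
    """Alphabetically first rotation of the (primitive) unit."""
    _check_unit(u)
    return min(rotations(primitive_unit(u)))


@lru_cache(maxsize=65536)
def canonical_type(u: str) -> str:
    """Alphabetically first rotation of the unit or its reverse complement."""
    p = primitive_unit(u)
    return min(canonical_motif(p), canonical_motif(reverse_complement(p)))


def repeat_class(u: str) -> int:
    """Unit size in bp (the repeat class)."""
    _check_unit(u)
    return len(u)


def is_palindromic_motif(u: str) -> bool:
    """True when the unit is rotation-equivalent to its reverse complement.

    Such motifs (e.g. AT) carry no strand information: motif and
    reverse-complement motif coincide.
    """
    return canonical_motif(u) == canonical_motif(reverse_complement(u))


def cyclic_rc_mismatches(u: str) -> int:
    """Minimum gapless Hamming distance between a unit and any cyclic
    rotation of its reverse complement.

    A value of 0 means the unit is a perfect cyclic palindrome (AT, ACGT
    ...); small values flag near-palindromic units that can fold into
    hairpin-like secondary structures.  Undefined for units containing N.
    """
    _check_unit(u)
    if "N" in u:
        raise ValueError("cyclic_rc_mismatches is undefined for units with N")
    rc = reverse_complement(u)
    return min(
        sum(a != b for a, b in zip(u, rot)) for rot in rotations(rc)
    )


@dataclass(frozen=True)
class CanonicalUnit:
    """A repeat unit together with its canonical forms."""

    unit: str

    @property
    def repeat_class(self) -> int:
        return repeat_class(self.unit)

    @property
    def repeat_type(self) -> str:
        return canonical_type(self.unit)

    @property
    def repeat_motif(self) -> str:
        return canonical_motif(self.unit)
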