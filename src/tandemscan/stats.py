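"""Aggregate statistics over detected tandem repeats.

The central quantity is the *density* of a set of repeats: the summed
repeat length per effective (non-N) megabase of sequence, in bp/Mbp.
Densities are additive over disjoint groupings, so type densities within
a repeat class sum to the class density and class densities sum to the
total.  Summaries also report counts, relative densities, mean/SD/max
lengths and mean perfection, grouped by repeat class, repeat type or
repeat motif, optionally per genomic region.

The strandedness table pairs every repeat motif with its
reverse-complement motif and reports both densities per region; on the
sense strands of annotated gene features a systematic difference within
a pair is evidence of strand-specific repeat usage.  Pair labels follow
the A/B/a/b scheme: A/B when both motif forms occur (A the normal form,
i.e. the type-canonical motif; B its reverse complement), a/b when only
one of the two is present, and "-" for palindromic motifs whose two
forms coincide.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .detect import RepeatHit
from .seq_io import SequenceRecord, effective_length
from .units import canonical_motif, canonical_type, is_palindromic_motif, reverse_complement

GroupBy = str  # "class" | "type" | "motif"

_GROUP_KEYS = {
    "class": lambda h: h.unit_size,
    "type": lambda h: (h.unit_size, h.repeat_type),
    "motif": lambda h: (h.unit_size, h.repeat_motif),
}


def density(hits: Iterable[RepeatHit], effective_bp: int) -> float:
    """Summed hit length per effective megabase, in bp/Mbp.

    NaN (missing) when the effective length is zero — never a division
    error, never silently 0.
    """
    total = sum(h.length for h in hits)
    if effective_bp == 0:
        return math.nan
    if effective_bp < 0:
        raise ValueError("effective_bp must be non-negative")
    return total / effective_bp * 1e6


def total_effective_length(seqs: Iterable[SequenceRecord]) -> int:
    return sum(effective_length(r) for r in seqs)


def summarize(
    hits: Sequence[RepeatHit],
    effective_bp: int,
    group_by: GroupBy = "class",
    sd_ddof: int = 0,
) -> pd.DataFrame:
    """One row per observed group: count, density, relative density,
    length statistics and mean perfection.

    ``sd_ddof=0`` gives the population SD of lengths (the default);
    pass 1 for the sample SD.  Mean perfection is unweighted over hits.
    Rows are ordered by class, then canonical string.
    """
    if group_by not in _GROUP_KEYS:
        raise ValueError(f"group_by must be one of {sorted(_GROUP_KEYS)}")
    key = _GROUP_KEYS[group_by]
    groups: dict[object, list[RepeatHit]] = {}
    for h in hits:
        groups.setdefault(key(h), []).append(h)
    total_len = sum(h.length for h in hits)
    rows = []
    for gkey in sorted(groups):
        ghits = groups[gkey]
        lengths = np.array([h.length for h in ghits], dtype=float)
        glen = lengths.sum()
        row = {
            "unit_size": gkey if group_by == "class" else gkey[0],
            "count": len(ghits),
            "density_bp_per_mbp": (glen / effective_bp * 1e6) if effective_bp else math.nan,
            "relative_density_pct": (100.0 * glen / total_len) if total_len else math.nan,
            "mean_length": lengths.mean(),
            "sd_length": lengths.std(ddof=sd_ddof) if len(lengths) > sd_ddof else math.nan,
            "max_length": int(lengths.max()),
            "mean_perfection": float(np.mean([h.perfection for h in ghits])),
        }
        if group_by != "class":
            row[group_by] = gkey[1]
        rows.append(row)
    cols = ["unit_size"] + ([group_by] if group_by != "class" else []) + [
        "count",
        "density_bp_per_mbp",
        "relative_density_pct",
        "mean_length",
        "sd_length",
        "max_length",
        "mean_perfection",
    ]
    return pd.DataFrame(rows, columns=cols)


def summarize_by_region(
    hits_by_region: Mapping[str, Sequence[RepeatHit]],
    effective_bp_by_region: Mapping[str, int],
    group_by: GroupBy = "class",
    sd_ddof: int = 0,
) -> pd.DataFrame:
    """Region-stratified summary: one row per (region, group)."""
    frames = []
    for region, hits in hits_by_region.items():
        df = summarize(hits, effective_bp_by_region[region], group_by, sd_ddof)
        df.insert(0, "region", region)
        frames.append(df)
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)


def unit_range_partition(
    class_summary: pd.DataFrame,
    ranges: Sequence[tuple[int, int]] = ((1, 6), (7, 10), (11, 50)),
) -> pd.DataFrame:
    """Density per unit-size range (e.g. 1-6 / 7-10 / 11-50 bp) with each
    range's percentage contribution to the total.  Ranges must be
    disjoint."""
    for i, (a, b) in enumerate(ranges):
        if a > b:
            raise ValueError(f"invalid range {(a, b)}")
        for a2, b2 in ranges[i + 1 :]:
            if a <= b2 and a2 <= b:
                raise ValueError(f"overlapping ranges {(a, b)} and {(a2, b2)}")
    dens = dict(
        zip(class_summary["unit_size"], class_summary["density_bp_per_mbp"])
    )
    total = sum(dens.values())
    rows = []
    for a, b in ranges:
        d = sum(v for k, v in dens.items() if a <= k <= b)
        rows.append(
            {
                "range": f"{a}-{b}",
                "unit_min": a,
                "unit_max": b,
                "density_bp_per_mbp": d,
                "contribution_pct": (100.0 * d / total) if total else 0.0,
            }
        )
    return pd.DataFrame(rows)


def _pair_label(motif: str, d_norm: float, d_rc: float) -> str:
    if is_palindromic_motif(motif):
        return "-"
    if d_norm > 0 and d_rc > 0:
        return "A/B"
    if d_norm > 0:
        return "a"
    if d_rc > 0:
        return "b"
    return ""


def strandedness_table(
    hits_by_region: Mapping[str, Sequence[RepeatHit]],
    effective_bp_by_region: Mapping[str, int],
) -> pd.DataFrame:
    """Motif-pair densities per region, for strandedness analysis.

    One row per repeat type observed anywhere; columns give, per region,
    the density of the normal-form motif (the type-canonical one) and of
    its reverse complement.  ``pair_label`` marks each pair: "-"
    palindromic, "A/B" both forms present (summed over regions), "a"
    normal form only, "b" reverse complement only.
    """
    regions = list(hits_by_region)
    per_motif: dict[str, dict[str, float]] = {r: {} for r in regions}
    types: set[str] = set()
    for region in regions:
        eff = effective_bp_by_region[region]
        groups: dict[str, int] = {}
        for h in hits_by_region[region]:
            groups[h.repeat_motif] = groups.get(h.repeat_motif, 0) + h.length
        for motif, glen in groups.items():
            per_motif[region][motif] = (glen / eff * 1e6) if eff else math.nan
            types.add(canonical_type(motif))
    rows = []
    for t in sorted(types, key=lambda t: (len(t), t)):
        motif_a = canonical_motif(t)  # normal form: the type itself
        motif_b = canonical_motif(reverse_complement(t))
        row: dict[str, object] = {
            "repeat_type": t,
            "motif_normal": motif_a,
            "motif_rc": motif_b,
        }
        tot_a = tot_b = 0.0
        for region in regions:
            da = per_motif[region].get(motif_a, 0.0)
            db = per_motif[region].get(motif_b, 0.0)
            row[f"{region}_normal"] = da
            row[f"{region}_rc"] = db
            tot_a += da if da == da else 0.0
            tot_b += db if db == db else 0.0
        row["pair_label"] = _pair_label(motif_a, tot_a, tot_b)
        rows.append(row)
    return pd.DataFrame(rows)
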