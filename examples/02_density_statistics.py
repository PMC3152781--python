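"""Density and length statistics of a repeat scan.

Generates a small synthetic genome with planted repeats, scans it, and
prints the per-class summary: counts, N-corrected densities in bp per
effective Mbp, relative densities (summing to 100%), mean/SD/max
lengths and mean perfection — plus the density split over the unit-size
ranges 1-6 / 7-10 / 11-50 bp.
"""

from tandemscan import find_repeats, make_fixture_genome, summarize, unit_range_partition
from tandemscan.stats import total_effective_length

bundle = make_fixture_genome(seed=7)
hits = [h for rec in bundle.sequences for h in find_repeats(rec)]
eff = total_effective_length(bundle.sequences)

print(f"{len(hits)} repeats in {eff} effective bp\n")
cls = summarize(hits, eff, group_by="class")
print(cls.round(2).to_string(index=False))
print("\nUnit-size range partition:")
print(unit_range_partition(cls).round(2).to_string(index=False))
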