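"""Region-stratified scanning and motif strandedness.

Splits a synthetic annotated genome into CDS / intron / UTR /
intergenic fragments (sense strand for gene-associated kinds), scans
each region separately, and prints the motif-pair strandedness table.
The fixture plants AAG arrays only on CDS sense strands, so AAG shows
density without its reverse complement CTT in CDS ("a" rows), while
intergenic sequence carries both forms.
"""

from tandemscan import extract_regions, find_repeats, make_fixture_genome, strandedness_table
from tandemscan.regions import fragments_to_records, region_effective_lengths

bundle = make_fixture_genome(seed=7)
frags = extract_regions(bundle.sequences, bundle.models)
eff = region_effective_lengths(frags)

hits_by_region = {}
for kind in ("CDS", "intron", "intergenic"):
    records = fragments_to_records(frags[kind])
    hits_by_region[kind] = [h for r in records for h in find_repeats(r)]
    print(f"{kind}: {len(frags[kind])} fragments, {eff[kind]} effective bp, "
          f"{len(hits_by_region[kind])} repeats")

print("\nMotif-pair densities (bp/Mbp); label: A/B both strands, a/b one strand, - palindromic")
table = strandedness_table(hits_by_region, eff)
print(table.round(1).to_string(index=False))
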