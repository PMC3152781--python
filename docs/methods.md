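# Methods

## Scoring model

A tandem repeat is scored by its best alignment against a perfect
tandem tiling of a repeat unit. Column scores default to match +1,
mismatch −5, gap −5, N 0. The "first unit unscored" convention is
implemented as `score = (sum of column scores) − unit_size ×
match_score`: for perfect repeats this equals leaving the first unit
out, it makes the score independent of which unit is called "first",
and it reproduces every threshold the defaults imply (smallest
qualifying perfect repeats of 13/14/15 bp for unit sizes 1/2/3; two
units for unit sizes > 12).

The qualifying rule is `score ≥ 12` for unit sizes ≤ 12 bp and `score ≥
unit size` above. Both the column scores and the rule are configurable
through `ScoringScheme`; the defaults are the configuration the rest of
this document assumes. Two presets cover the usual unit-size ranges:
1–50 bp with unlimited maximum score reduction, and 1–4000 bp with the
reduction capped at 30.

## Search strategy

**Seeds.** For each unit size *p* the scanner finds maximal runs of
in-phase equalities `s[i] == s[i+p]` (N positions excluded) of length
at least `min(p, 4)` — a perfect tandem of two units, or enough perfect
copies to score 4, whichever is shorter. Every candidate starts from
such a seed with the literal unit read at the seed start.

**Extension.** From each seed edge, extension proceeds in *segments*: a
bundle of 1..`recursion_depth` (default 5) consecutive edit columns
(mismatch, insertion, deletion) followed by a maximal run of match/N
columns. A segment is appended only when it strictly raises the
running score. All improving continuations are explored; branches meet
in a per-(position, phase) best-score memo, so the closure is computed
exactly and deterministically. Ties on final score prefer the farther
endpoint, then the smaller phase index. Because every accepted segment
improves on the previous peak, the running score along a chain peaks at
each segment boundary; the *maximum score reduction* (X-drop) rule
therefore reduces to discarding bundles whose cumulative penalty
exceeds the cap. With the default depth of 5 and penalty −5 a cap of
30 almost never binds — it matters when deeper recursion or milder
penalties are configured. This segment-wise rule is what makes
termination local (junk flanks stop extension after one failed bundle
round) and whole-genome scanning linear-time; it also means an
extension requiring a non-improving intermediate segment before a
distant recovery is, by definition, not taken.

**N handling.** N columns score `n_score` (default 0), never count as
edits, and runs longer than `max_successive_ns` (default 4) columns are
never crossed, so four Ns can bridge two repeat stretches (a 44 bp
(AC)₁₀+NNNN+(AC)₁₀ region scores 38 as one hit) and five Ns always
split them.

**Consensus and bookkeeping.** The reported unit is the per-position
majority over aligned unit copies (ties alphabetical), rotated into
the phase at the hit start. Perfection is 100 × matches / total
alignment columns, the unscored first unit included, so perfect repeats
read exactly 100%. Coordinates are 0-based half-open in the API and
1-based inclusive in files.

**Overlap resolution.** Candidates from all unit sizes are pooled;
identical intervals are collapsed (best score, then smaller unit);
among overlapping hits the higher score wins, ties to the smaller unit
size, then the leftmost start. Losing same-interval readings survive in
the winner's `alternatives`, which also lists divisor/multiple unit
sizes of the winner whose anchored unit is primitive and whose
same-interval score either qualifies on its own or lies within five
edits' worth (25) of the primary — the window is a design choice that
keeps hopeless readings (e.g. a mononucleotide view of (ACACAT)ₙ at
−72) out of the reports while preserving informative ones (the −2
dinucleotide view).

**Known limitation.** A repeat whose longest perfect stretch is shorter
than one unit plus `min(p, 4)` bases has no seed and is missed. Under
the default penalties such repeats need ≥ 5 edits per recovered stretch
and barely qualify; the synthetic generator spaces edits so planted
repeats are always seedable, and the brute-force oracle shares the seed
rule, so tests quantify the search bookkeeping, not this boundary.

## Reference oracle

`naive_oracle` re-derives detection on small inputs (≤ 500 bp by
default) with deliberately naive machinery: literal character scans for
seeds, explicit enumeration of every edit bundle as op-strings, a
breadth-first closure without pruning or memo shortcuts. It shares only
the scheme definition and the overlap-resolution plumbing with the
production path. The two implementations agree on every instance of a
1000-sequence seeded sweep (random sequences with planted arrays and N
patches, units 1–6); this validates seeding completeness, phase
bookkeeping, X-drop pruning and deduplication in the fast path. Note
the oracle enumerates the same improving-segment alignment space — an
unrestricted interval DP would be a *different* semantics that accepts non-improving intermediate segments, and is
deliberately not used as the reference.

## Statistics

Density is Σ(hit lengths) / effective length × 10⁶ in bp/Mbp, where
effective length excludes Ns; appending Ns to a sequence provably
changes nothing. Group summaries (by repeat class, type or motif,
optionally per region) report counts, density, relative density (sums
to 100% over an exhaustive grouping), mean/SD/max length and mean
perfection. Two conventions the tables need but that could be chosen
either way are fixed as: **population SD** of lengths (`sd_ddof=0`,
switchable), and **unweighted** mean perfection over hits. Summaries
are computed on the non-overlapping post-resolution hit set by default
(coverage can then never exceed 100%); callers may pass any hit list,
including a pre-resolution one, for sensitivity analysis. Counts are
counts of resolved hits.

The strandedness table pairs each motif with its reverse-complement
motif per region and labels pairs A/B (both present), a (normal form
only), b (reverse complement only), "-" (palindromic, the two forms
coincide). The normal form of a pair is the type-canonical motif.

## Region pipeline

Gene models are read from GFF (GFF3 `Parent=` links or GTF-style
attributes; one model per transcript). Cleanup is deterministic:
same-strand overlapping models lose the *longer genomic span*
(iterated until stable; equal spans drop the rightmost); within a
model, overlapping same-type features likewise lose the longer one
(equal lengths keep the leftmost). "Length" means genomic span, not
summed exon length — the natural reading when only span overlap is
observable. Opposite-strand overlaps (nested genes) are kept. Introns
are inter-exon gaps; UTRs are inferred from start/stop codons where
annotated (models whose codons fall outside exons are flagged and get
no UTRs); intergenic regions are the complement of deduplicated gene
spans and carry no strand. Region-stratified repeat statistics are
computed by running detection *inside* extracted fragments, so repeats
are truncated at region boundaries by construction — the same behaviour
as scanning per-region sequence files. Stranded kinds carry the sense
strand (minus-strand fragments reverse-complemented); exon fragments
are produced but excluded from combined reports since their repeat
content is the union of CDS and UTR content.

## Synthetic data

The generator emulates genome fragments with known repeat content: an
i.i.d. background at a requested GC content (default 0.40, a typical
AT-rich invertebrate value), three-exon gene models alternating
strands with codon-annotated UTRs, and plants placed inside requested
region kinds with ≥ 25 bp padding. Defaults are deliberately modest —
one 30 kbp sequence, four genes, a dozen plants spanning classes 1–17
including a sense-strand-only AAG bias in CDS — because every statistic
in scope is size-invariant; the layout still exercises each region
kind, both strands, palindromic and strand-asymmetric motifs, and an
N-containing plant.

Edits are applied outside the first unit, at least one unit + 4 bp from
the plant start (a seed always survives), at least 6 intact columns
after each edit and before the end (every edit is bridged by an
improving segment), and N runs never exceed the detector's cap. Under
these constraints the expected score and perfection follow exactly from
the column ledger (substitution/deletion −6, insertion −5, N column
−1 relative to the perfect plant), and requests that violate them are
refused rather than silently degraded. Guard bases at both plant edges
break the unit period so chance continuation cannot shift the truth
interval. Because a random background can still, rarely, extend a plant
through a chance run of in-phase matches, whole fixtures are by default
*verified*: the fixture is re-drawn (bounded retries, seeded) until the
detector recovers every plant exactly. Verification only rejects
background luck; a systematic detector/generator disagreement exhausts
the retry budget and fails loudly.

What synthetic fixtures do not emulate: compositional heterogeneity
and isochores, repeat families with homologous (rather than random)
flanks, nested or adjacent repeat arrays, slippage-generated length
polymorphism, and realistic gene architecture diversity. Passing tests
therefore demonstrate correctness of detection, bookkeeping and
statistics — not calibration of biological expectations.

## Problem sizes in the test suite

The suites run at sizes chosen to exercise every code path while
keeping the default test run quick: the oracle sweep uses 1000
sequences of 40–500 bp (units 1–6); planted-repeat recovery uses 100
verified fixtures of ~1.2–2 kbp spanning unit sizes 1–50 with
mismatch/indel/N edits; conservation, symmetry and region-partition
laws run on a shared 30 kbp annotated fixture. The acceptance script
scans array lengths up to 60 bp and 17-rotation mismatch counts —
all exact computations.
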