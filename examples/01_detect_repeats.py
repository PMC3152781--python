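"""Detect perfect and imperfect tandem repeats in a small sequence.

Builds a 24 bp hexanucleotide array inside random flanks, runs the
detector, and prints each hit.  The (ACACAT)x4 array is reported as a
perfect hexamer (score 18 = 24 bp minus one unscored unit) and the
alternative reading as an imperfect dinucleotide appears with its much
lower score (-2), illustrating the alignment-score optimality rule.
"""

import numpy as np

from tandemscan import ScoringScheme, SequenceRecord, find_repeats

rng = np.random.default_rng(1)
flank = lambda n: "".join(rng.choice(list("GT"), size=n))
seq = SequenceRecord("demo", flank(40) + "ACACAT" * 4 + flank(40))

for hit in find_repeats(seq, ScoringScheme()):
    print(
        f"{hit.sequence_id}:{hit.start + 1}-{hit.end}  unit={hit.unit} "
        f"(class {hit.unit_size}, type {hit.repeat_type}, motif {hit.repeat_motif})"
    )
    print(
        f"  score={hit.score}  length={hit.length}  copies={hit.copy_number:.1f}  "
        f"perfection={hit.perfection:.1f}%"
    )
    print(f"  alternative readings (unit_size, score): {hit.alternatives}")
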