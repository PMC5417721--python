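"""Select top motifs under a coverage budget and score them against
annotated binding sites.

Positives carry a planted window whose interval doubles as the "annotated"
site; after discovery, motifs are selected in rank order until their
coverage approaches the budget, and every covered residue's distance to the
nearest site is summarized.
"""

import numpy as np

from linmotif import (
    BindingSiteAnnotation,
    ProteomePartition,
    RunConfig,
    SequenceRecord,
    discover,
    overlap_with_sites,
    select_top,
)
from linmotif.motif import AMINO_ACIDS

rng = np.random.default_rng(23)

positives, sites = [], []
for i in range(25):
    chars = list(rng.choice(list(AMINO_ACIDS), size=150))
    off = int(rng.integers(0, 146))
    chars[off : off + 4] = "PQLP"
    positives.append(SequenceRecord(f"pos{i}", "".join(chars)))
    sites.append(BindingSiteAnnotation(f"pos{i}", off, off + 4))

partition = ProteomePartition(
    target_id="demo",
    positives=positives,
    negatives=[
        SequenceRecord(f"neg{i}", "".join(rng.choice(list(AMINO_ACIDS), size=150)))
        for i in range(40)
    ],
    background=[],
)

result = discover(partition, RunConfig(lmin=3, lmax=4, min_occurrence=3))
report = select_top(result.ranked, positives, budget_fraction=0.03)
pct_within, pct_within_10, histogram = overlap_with_sites(report, sites)

print(f"selected {len(report.selected)} motifs:",
      ", ".join(str(s.motif) for s in report.selected))
print(f"covered {report.n_covered} residues "
      f"({report.pct_of_positives_covered:.2f}% of the positives)")
print(f"within sites: {pct_within:.1f}%   within 10 aa: {pct_within_10:.1f}%")
print("distance histogram:", {k: round(v, 3) for k, v in histogram.items()})

# With the planted window as the only real signal, nearly all residues
# covered by the selected motifs fall inside the annotated intervals
# (distance bin 0), mirroring a discovered-motif-vs-known-sites evaluation.
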