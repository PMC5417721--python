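"""Discover enriched motifs in a small synthetic proteome partition.

Thirty "binder" proteins share a planted PxxP-style window; negatives and
background are random. The pipeline enumerates every wildcard-masked motif
of lengths 3-5, scores hypergeometric enrichment on both reference sets and
ranks by the weaker population z-score.
"""

import numpy as np

from linmotif import ProteomePartition, RunConfig, SequenceRecord, discover
from linmotif.motif import AMINO_ACIDS

rng = np.random.default_rng(7)


def random_protein(name, length=120):
    return SequenceRecord(name, "".join(rng.choice(list(AMINO_ACIDS), size=length)))


positives = []
for i in range(30):
    rec = random_protein(f"pos{i}")
    chars = list(rec.residues)
    off = int(rng.integers(0, 116))
    chars[off : off + 4] = "PQLP"  # the shared binding window
    positives.append(SequenceRecord(rec.id, "".join(chars)))

partition = ProteomePartition(
    target_id="SH3_demo",
    positives=positives,
    negatives=[random_protein(f"neg{i}") for i in range(20)],
    background=[random_protein(f"bak{i}") for i in range(50)],
)

result = discover(partition, RunConfig(lmin=3, lmax=5, min_occurrence=3))

print(f"population: {result.population_size} motifs over {result.n_masks} mask passes")
print(f"{'motif':12s} {'k':>3} {'q':>3} {'m':>3} {'log10 pNEG':>11} {'log10 pBAK':>11} {'z':>6}")
for sm in result.top(5):
    print(
        f"{str(sm.motif):12s} {sm.counts.k_pos:3d} {sm.counts.q_neg:3d} "
        f"{sm.counts.m_bak:3d} {sm.log10_p_neg:11.2f} {sm.log10_p_bak:11.2f} {sm.z:6.2f}"
    )

# The planted window PQLP (and its masked relatives such as PxLP or PQxP)
# should dominate: present in all 30 positives, nearly absent elsewhere,
# with p-values tens of orders of magnitude below any chance motif.
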