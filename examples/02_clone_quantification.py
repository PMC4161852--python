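"""Clone-level methylation calling: from sequenced molecules to proportions.

Simulates a handful of bisulfite-sequenced clones for two samples, renders
them as sequences, calls each clone back from its sequence and assembles the
per-sample methylation-proportion matrix.
"""

import numpy as np

from qbgs.quant import call_clone_pattern, filter_clones, proportions_from_clones
from qbgs.reference import ReferenceSequence, enumerate_cpgs
from qbgs.simulate import render_clone_sequence, simulate_clones

ref = ReferenceSequence(
    "demo_amplicon",
    "ATTGACGTTAGGTCATTCGATTGGATCAGGTACGTTAGGACGATTCCATTAGGTTCGAAGGTTACGGATTCACGGATTA",
)
cmap = enumerate_cpgs(ref)
print(f"amplicon: {len(ref)} bp, {cmap.n_sites} CpG sites")

rng = np.random.default_rng(7)
patterns = []
for sid, level in [("methylated_case", 0.8), ("unmethylated_case", 0.1)]:
    for pat in simulate_clones(np.full(cmap.n_analyzed, level), 12, rng, sid):
        seq = render_clone_sequence(pat, ref, cmap)  # what the sequencer returns
        patterns.append(call_clone_pattern(seq, ref, cmap, sample_id=sid, clone_id=pat.clone_id))

kept = filter_clones(patterns, min_conversion=0.95)
matrix = proportions_from_clones(kept)

print("\nlollipop view (rows = clones, M methylated / u unmethylated):")
for pat in patterns[:4]:
    print("  ", "".join("M" if c == 1 else "u" for c in pat.calls), pat.clone_id)

print("\nper-sample methylation proportions (first 6 sites):")
print(matrix.proportions.iloc[:, :6].round(2))
# Each cell is the fraction of that sample's clones methylated at the site --
# the quantity all survival modelling downstream runs on.
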