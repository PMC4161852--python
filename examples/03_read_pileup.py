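"""Read-level methylation calling: deep-sequencing pileup over CpG columns.

Simulates amplicon reads from a clone mixture (with conversion failures and
sequencing errors), piles them over the CpG columns and compares the
read-derived proportions with the clone-mixture truth.
"""

import numpy as np

from qbgs.quant import matrix_from_reads, proportions_from_clones
from qbgs.reference import ReferenceSequence, enumerate_cpgs
from qbgs.simulate import simulate_clones, simulate_reads

ref = ReferenceSequence(
    "demo_amplicon",
    "ATTGACGTTAGGTCATTCGATTGGATCAGGTACGTTAGGACGATTCCATTAGGTTCGAAGGTTACGGATTCACGGATTA",
)
cmap = enumerate_cpgs(ref)

rng = np.random.default_rng(11)
clones = simulate_clones(rng.uniform(0.2, 0.8, cmap.n_analyzed), 30, rng, "S1")
truth = proportions_from_clones(clones).proportions

reads = simulate_reads(
    clones, ref, cmap, depth=800, conversion_failure=0.01, sequencing_error=0.005, rng=rng
)
matrix = matrix_from_reads({"S1": reads}, ref, cmap, min_depth=100)

print(f"{len(reads)} reads piled over {cmap.n_analyzed} CpG columns")
print("\nsite  truth  read-based  depth")
for label in truth.columns[:8]:
    print(
        f"CpG{label:<3d} {truth.loc['S1', label]:.3f}   "
        f"{matrix.proportions.loc['S1', label]:.3f}     "
        f"{matrix.denominators.loc['S1', label]}"
    )
err = np.abs(matrix.proportions.loc["S1"] - truth.loc["S1"]).max()
print(f"\nmax |read - clone| deviation: {err:.3f}")
# At depth ~800 the pileup estimate tracks the clone-mixture truth to within
# binomial noise even with 1% conversion failure and 0.5% sequencing error.
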