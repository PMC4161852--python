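"""Ward clustering of methylation profiles and pairwise cluster survival.

Clusters a synthetic cohort into four methylation-level groups (1 = most
methylated) and compares survival between every pair of clusters.
"""

import numpy as np

from qbgs.cluster import pairwise_survival, ward_clusters
from qbgs.simulate import graded_hazard_config, simulate_cohort

cohort = simulate_cohort(graded_hazard_config(n_samples=80), seed=3)
result = ward_clusters(cohort.matrix, k=4)

sizes = np.bincount(result.labels)[1:]
X = cohort.matrix.proportions.to_numpy()
print("cluster  n   mean methylation")
for c in (1, 2, 3, 4):
    print(f"   {c}    {sizes[c - 1]:3d}    {X[result.labels == c].mean():.3f}")

P = pairwise_survival(result, cohort.surv_pfs)
print("\npairwise PFS log-rank p-values:")
print(P.round(4))
print(
    "\nsmallest p:",
    f"{np.nanmin(P.to_numpy()):.2e}",
    "(clusters 1 vs 4 — the methylation extremes)",
)
# Cluster 1 (strongly methylated) progresses slowest; the extreme pair is the
# most separated, mirroring how methylation level grades prognosis.
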