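"""Per-CpG survival screening: univariate Cox with the score (log-rank) test.

Generates a cohort whose progression hazard is protective in ten CpG sites
of the classifier window and screens all 77 sites against PFS.
"""

from qbgs.simulate import graded_hazard_config, simulate_cohort
from qbgs.survival import screen_sites

cfg = graded_hazard_config(n_samples=53)
cohort = simulate_cohort(cfg, seed=5)
result = screen_sites(cohort.matrix, cohort.surv_pfs, alpha=0.05)

print(f"screened {len(result.table)} sites; {len(result.selected)} at p < 0.05")
print("\ntop 10 sites by score-test p:")
print(result.table.head(10).to_string(index=False, float_format=lambda v: f"{v:.4g}"))

truth = set(cfg.prognostic_sites)
hits = truth & set(result.selected)
print(f"\ntruly prognostic sites recovered: {len(hits)} of {len(truth)}: {sorted(hits)}")
# Negative coefficients mean higher methylation lowers progression hazard
# (protective); archetype correlation also drags neighbouring sites along,
# which is why more than the ten causal sites reach significance.
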