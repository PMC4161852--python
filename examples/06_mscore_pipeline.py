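"""The M-score classifier end-to-end: LOOCV, final model, test-set validation.

Trains on a 53-sample synthetic cohort (clone-level qBGS), evaluates by
leave-one-out cross-validation, fixes the final model (full-cohort Cox
weights; threshold = mean of the fold thresholds) and classifies an
independently generated 32-sample test cohort.
"""

import logging
from dataclasses import replace

from qbgs.mscore import classify, evaluate_split, fit_final_model, loocv

# near-separated site fits are routine under the strong-signal scenario
# (their coefficients are zeroed); silence the per-fold notices
logging.getLogger("qbgs").setLevel(logging.ERROR)
from qbgs.simulate import simulate_cohort, strong_signal_config

SITES = tuple(range(51, 75))  # CpG51-CpG74, the sequencer-constrained window

cfg = strong_signal_config(n_samples=53)
train = simulate_cohort(cfg, seed=1)

cv = loocv(train.matrix, train.surv_pfs, train.surv_os, SITES)
print("LOOCV on the training cohort:")
for endpoint, (chi2, p) in cv.logrank_by_endpoint.items():
    print(f"  {endpoint}: predicted-class log-rank p = {p:.4g}")

model = fit_final_model(train.matrix, train.surv_pfs, SITES, loocv_result=cv)
print(f"\nfinal model: threshold tau = {model.threshold:.2f}, "
      f"good prognosis = score {'<=' if model.good_side == 'below' else '>'} tau")

test = simulate_cohort(replace(cfg, n_samples=32), seed=2)
calls = classify(model, test.matrix)
n_good = sum(v == "good" for v in calls.values())
_, p = evaluate_split(calls, test.surv_pfs)
print(f"\ntest cohort: {n_good} good / {32 - n_good} poor prognosis")
print(f"test-set PFS log-rank p = {p:.4g}")
# A small test p confirms the weights and threshold learned on the training
# cohort transfer to unseen samples drawn from the same population.
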