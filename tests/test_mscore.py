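"""M-score computation, threshold selection, LOOCV and classification."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test

from qbgs.mscore import (
    DegenerateScoresError,
    LOOCVResult,
    MScoreModel,
    classify,
    evaluate_split,
    fit_final_model,
    loocv,
    mscore,
    select_threshold,
)
from qbgs.quant import MethylationMatrix
from qbgs.simulate import simulate_cohort, strong_signal_config
from qbgs.survival import SurvivalTable, fit_cox_univariate


def test_mscore_linear_arithmetic():
    assert mscore(np.zeros(5), np.zeros(5)) == 0.0
    assert mscore(np.array([0.5, 0.25]), np.array([1.0, 2.0])) == 1.0
    x, a = np.array([0.2, 0.6, 0.9]), np.array([1.5, -2.0, 0.3])
    perm = [2, 0, 1]
    assert mscore(x[perm], a[perm]) == pytest.approx(mscore(x, a))
    assert mscore(x, 3 * a) == pytest.approx(3 * mscore(x, a))


def test_mscore_missing_policy():
    a = np.ones(8)
    x = np.full(8, 0.5)
    x[0] = np.nan
    means = np.full(8, 0.25)
    assert mscore(x, a, impute=means) == pytest.approx(0.5 * 7 + 0.25)
    x[:3] = np.nan  # 3/8 > 25% missing -> unscorable
    assert np.isnan(mscore(x, a, impute=means))


def _surv(times, events, ids=None):
    ids = ids or [f"s{i}" for i in range(len(times))]
    return SurvivalTable(ids, np.asarray(times, float), np.asarray(events))


def test_select_threshold_degenerate():
    with pytest.raises(DegenerateScoresError):
        select_threshold(np.ones(6), _surv([1, 2, 3, 4, 5, 6], [1] * 6))


def test_select_threshold_matches_exhaustive_oracle():
    """8-sample toy: the 4-vs-4 split is optimal; p equals the brute-force
    minimum over all 7 admissible splits (lifelines as oracle)."""
    scores = np.arange(1.0, 9.0)
    times = np.array([20, 22, 24, 26, 2, 3, 4, 5.0])
    surv = _surv(times, np.ones(8, int))
    tau, p = select_threshold(scores, surv)
    oracle = []
    for c in scores[:-1]:
        low = scores <= c
        r = logrank_test(times[low], times[~low], np.ones(low.sum()), np.ones((~low).sum()))
        oracle.append((r.p_value, c))
    best_p, best_c = min(oracle)
    assert tau == best_c == 4.0
    assert p == pytest.approx(best_p, abs=1e-12)


def test_select_threshold_tie_resolved_by_median():
    """Mirror-symmetric toy: splits 1|234 and 123|4 tie exactly, so the
    median of the tied candidates (2.0) is returned."""
    scores = np.array([1.0, 2.0, 3.0, 4.0])
    surv = _surv([1, 5, 5, 1], [1, 1, 1, 1])
    tau, p = select_threshold(scores, surv)
    assert tau == 2.0


def test_select_threshold_monotone_transform_invariance():
    rng = np.random.default_rng(42)
    scores = rng.normal(size=20)
    surv = _surv(rng.exponential(10, 20), rng.integers(0, 2, 20) | 1)
    tau, p = select_threshold(scores, surv)
    tau_t, p_t = select_threshold(np.exp(scores), surv)
    assert p_t == pytest.approx(p, abs=1e-12)
    assert np.array_equal(scores <= tau, np.exp(scores) <= tau_t)


def _cohort_matrix(coh):
    return coh.matrix


def test_loocv_structure_and_order_invariance():
    coh = simulate_cohort(strong_signal_config(n_samples=30), 5)
    sites = range(51, 75)
    res = loocv(coh.matrix, coh.surv_pfs, coh.surv_os, sites)
    assert len(res.classes) == 30
    assert res.n_unclassified == 0
    # shuffling the sample order changes nothing per-sample
    rng = np.random.default_rng(0)
    perm = rng.permutation(coh.sample_ids).tolist()
    mat2 = MethylationMatrix(
        coh.matrix.proportions.loc[perm], coh.matrix.denominators.loc[perm]
    )
    res2 = loocv(mat2, coh.surv_pfs, coh.surv_os, sites)
    by_id = dict(zip(res.sample_ids, res.classes))
    by_id2 = dict(zip(res2.sample_ids, res2.classes))
    assert by_id == by_id2
    assert res.logrank_by_endpoint["PFS"] == pytest.approx(
        res2.logrank_by_endpoint["PFS"]
    )


def test_loocv_fold_isolation():
    """Fold i never reads sample i's survival: perturbing it leaves fold i's
    threshold and sample i's predicted class unchanged."""
    coh = simulate_cohort(strong_signal_config(n_samples=25), 7)
    sites = range(51, 75)
    res = loocv(coh.matrix, coh.surv_pfs, None, sites)
    i = 3
    t2 = coh.surv_pfs.time.copy()
    e2 = coh.surv_pfs.event.copy()
    t2[i] = 77.7
    e2[i] = 1 - e2[i]
    perturbed = SurvivalTable(coh.surv_pfs.sample_ids, t2, e2, "PFS")
    res2 = loocv(coh.matrix, perturbed, None, sites)
    assert res2.fold_thresholds[i] == res.fold_thresholds[i]
    assert res2.classes[i] == res.classes[i]


def test_fit_final_model_structural_identities():
    coh = simulate_cohort(strong_signal_config(n_samples=40), 11)
    sites = tuple(range(51, 75))
    res = loocv(coh.matrix, coh.surv_pfs, None, sites)
    model = fit_final_model(coh.matrix, coh.surv_pfs, sites, loocv_result=res)
    # threshold is the mean of the fold thresholds, by definition
    valid = ~np.isnan(res.fold_thresholds)
    assert model.threshold == pytest.approx(res.fold_thresholds[valid].mean())
    # coefficients equal site-by-site full-cohort univariate fits
    surv = coh.surv_pfs.align(coh.sample_ids)
    X = coh.matrix.subset(sites).proportions.to_numpy()
    for j in (0, 5, 23):
        f = fit_cox_univariate(X[:, j], surv)
        expected = f.coef if f.converged else 0.0
        assert model.coefficients[j] == pytest.approx(expected, rel=1e-9)


def test_final_model_sign_recovery():
    """Protective prognostic sites: fitted coefficient signs match the
    generating beta for >= 90% of prognostic sites at n = 200."""
    cfg = strong_signal_config(n_samples=200)
    coh = simulate_cohort(cfg, 19)
    res = loocv(coh.matrix, coh.surv_pfs, None, range(51, 75))
    model = fit_final_model(coh.matrix, coh.surv_pfs, tuple(range(51, 75)), res)
    idx = [s - 51 for s in cfg.prognostic_sites]
    signs = np.sign(model.coefficients[idx])
    assert (signs == np.sign(cfg.beta_per_site)).mean() >= 0.9


def test_classify_boundary_and_roundtrip():
    model = MScoreModel(
        sites=(1, 2),
        coefficients=np.array([1.0, -1.0]),
        threshold=0.1,
        good_side="below",
        training_means=np.array([0.5, 0.5]),
    )
    mat = MethylationMatrix(
        pd.DataFrame([[0.0, 0.0], [0.9, 0.1]], index=["z", "h"], columns=[1, 2]),
        pd.DataFrame(9, index=["z", "h"], columns=[1, 2]),
    )
    out = classify(model, mat)
    assert out["z"] == "good"  # score 0 <= tau on the good side
    assert out["h"] == "poor"  # score 0.8 > tau
    # exact-threshold score lands on the <= side
    model2 = MScoreModel((1, 2), np.array([1.0, 1.0]), 1.0, "above")
    mat2 = MethylationMatrix(
        pd.DataFrame([[0.5, 0.5]], index=["t"], columns=[1, 2]),
        pd.DataFrame(9, index=["t"], columns=[1, 2]),
    )
    assert classify(model2, mat2)["t"] == "poor"


def test_training_reclassification_consistency():
    coh = simulate_cohort(strong_signal_config(n_samples=40), 23)
    sites = tuple(range(51, 75))
    model = fit_final_model(coh.matrix, coh.surv_pfs, sites)
    out = classify(model, coh.matrix)
    X = coh.matrix.subset(sites).proportions.to_numpy()
    scores = X @ model.coefficients
    for sid, s in zip(coh.sample_ids, scores):
        low = s <= model.threshold
        expected = "good" if (model.good_side == "below") == low else "poor"
        assert out[sid] == expected


def test_heldout_validation_split():
    """Fresh synthetic test cohorts (n=32) separate by PFS log-rank p<0.05
    in >= 80% of seeds under the strong-signal scenario."""
    cfg = strong_signal_config(n_samples=100)
    hits = 0
    n_seeds = 50
    for seed in range(n_seeds):
        train = simulate_cohort(cfg, 1000 + seed)
        model = fit_final_model(train.matrix, train.surv_pfs, tuple(range(51, 75)))
        test = simulate_cohort(replace(cfg, n_samples=32), 2000 + seed)
        out = classify(model, test.matrix)
        if len({v for v in out.values()}) < 2:
            continue
        _, p = evaluate_split(out, test.surv_pfs)
        hits += p < 0.05
    assert hits >= 0.8 * n_seeds


def test_model_json_roundtrip(tmp_path):
    model = MScoreModel(
        sites=(51, 52),
        coefficients=np.array([0.5, -1.25]),
        threshold=2.2,
        good_side="above",
        training_means=np.array([0.4, 0.6]),
        provenance={"n_training_samples": 53},
    )
    path = tmp_path / "model.json"
    model.to_json(path)
    back = MScoreModel.from_json(path)
    assert back.sites == model.sites
    assert np.allclose(back.coefficients, model.coefficients)
    assert back.threshold == model.threshold
    assert back.good_side == model.good_side
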