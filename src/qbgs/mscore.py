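"""The M-score prognostic classifier.

The M-score of a sample is a weighted sum of its methylation proportions over
a fixed CpG-site window,

    M = sum_i A_i * X_i ,

where each weight ``A_i`` is the coefficient of a *univariate* Cox regression
of progression-free survival on the methylation proportion at site *i*, fit on
the training cohort.  Patients are split into good and poor prognosis groups
at a threshold tau chosen to minimise the two-group log-rank p over the
observed training scores (ties on p resolved by the median tied score), and
the procedure is evaluated by leave-one-out cross-validation: for each held
out sample, weights, threshold and group orientation are re-derived from the
remaining samples only.

Which side of tau is "good" is learned from the training split (the side with
the longer Kaplan-Meier median survival, restricted-mean as tie-break): the
sign convention of the published weights cannot be assumed, so orientation is
data-driven rather than hard-coded.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .quant import MethylationMatrix
from .survival import (
    SurvivalTable,
    cox_univariate_many,
    kaplan_meier,
    logrank_scan,
    restricted_mean_survival,
)
from scipy import stats

__all__ = [
    "MScoreModel",
    "LOOCVResult",
    "DegenerateScoresError",
    "mscore",
    "select_threshold",
    "loocv",
    "fit_final_model",
    "classify",
]

logger = logging.getLogger(__name__)

_MAX_MISSING_FRACTION = 0.25


class DegenerateScoresError(ValueError):
    """Threshold selection is impossible (all scores identical / no split)."""


@dataclass
class MScoreModel:
    """Site subset, per-site Cox weights, threshold and good-prognosis side."""

    sites: tuple[int, ...]
    coefficients: np.ndarray
    threshold: float
    good_side: str  # "below": score <= tau is the good-prognosis group
    endpoint: str = "PFS"
    training_means: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (len(self.sites),):
            raise ValueError("one coefficient per subset site required")
        if self.good_side not in ("above", "below"):
            raise ValueError("good_side must be 'above' or 'below'")
        if self.training_means is not None:
            self.training_means = np.asarray(self.training_means, dtype=float)

    def to_json(self, path=None) -> str:
        payload = {
            "format": "qbgs-mscore-model/1",
            "sites": [int(s) for s in self.sites],
            "coefficients": [float(c) for c in self.coefficients],
            "threshold": float(self.threshold),
            "good_side": self.good_side,
            "endpoint": self.endpoint,
            "training_means": (
                None if self.training_means is None
                else [float(m) for m in self.training_means]
            ),
            "provenance": self.provenance,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "MScoreModel":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        if payload.get("format") != "qbgs-mscore-model/1":
            raise ValueError("unrecognised model file format")
        means = payload.get("training_means")
        return cls(
            sites=tuple(payload["sites"]),
            coefficients=np.array(payload["coefficients"], dtype=float),
            threshold=float(payload["threshold"]),
            good_side=payload["good_side"],
            endpoint=payload.get("endpoint", "PFS"),
            training_means=None if means is None else np.array(means, float),
            provenance=payload.get("provenance", {}),
        )


@dataclass
class LOOCVResult:
    """Per-fold predictions and the overall predicted-class survival split."""

    sample_ids: list[str]
    classes: list[str | None]  # "good" / "poor" / None (unclassified)
    fold_thresholds: np.ndarray  # NaN where a fold degenerated
    fold_good_sides: list[str | None]
    scores: np.ndarray  # held-out M-scores
    logrank_by_endpoint: dict  # endpoint -> (chi2, p)

    @property
    def n_unclassified(self) -> int:
        return sum(c is None for c in self.classes)


def mscore(
    x: np.ndarray,
    coefficients: np.ndarray,
    impute: np.ndarray | None = None,
) -> float:
    """Weighted sum ``sum_i A_i x_i`` over the site subset.

    Missing proportions are imputed from ``impute`` (training means) when at
    most 25% of subset sites are missing; beyond that the sample is
    unscorable and NaN is returned.
    """
    x = np.asarray(x, dtype=float)
    a = np.asarray(coefficients, dtype=float)
    if x.shape != a.shape:
        raise ValueError("proportions and coefficients must align")
    missing = np.isnan(x)
    if missing.any():
        if missing.mean() > _MAX_MISSING_FRACTION or impute is None:
            return float("nan")
        x = np.where(missing, impute, x)
    return float(x @ a)


def _scores_for_rows(X: np.ndarray, coefs: np.ndarray, means: np.ndarray) -> np.ndarray:
    return np.array([mscore(row, coefs, impute=means) for row in X])


def select_threshold(
    scores: np.ndarray,
    surv: SurvivalTable,
    min_group: int = 1,
) -> tuple[float, float]:
    """Pick the score threshold minimising the two-group log-rank p.

    Candidates are the observed scores; each splits samples into
    ``score <= tau`` versus ``score > tau`` (empty-group candidates skipped).
    Among candidates tied exactly on the minimum p, the median tied value is
    returned (mean of the two middle values at even counts).
    """
    scores = np.asarray(scores, dtype=float)
    if len(scores) != len(surv):
        raise ValueError("scores and survival table differ in length")
    if np.unique(scores).size < 2:
        raise DegenerateScoresError("all scores identical; no admissible split")
    cands, chi2, p = logrank_scan(scores, surv, min_group=min_group)
    if cands.size == 0:
        raise DegenerateScoresError("no admissible split under min_group")
    pmin = p.min()
    tied = cands[p == pmin]
    return float(np.median(tied)), float(pmin)


def _good_side(scores, tau, surv) -> str:
    """Orientation of the good-prognosis group: longer median KM survival."""
    low = scores <= tau
    km_low = kaplan_meier(surv.mask(low))
    km_high = kaplan_meier(surv.mask(~low))
    m_low, m_high = km_low.median, km_high.median
    if m_low != m_high:
        return "below" if m_low > m_high else "above"
    horizon = float(surv.time.max())
    return (
        "below"
        if restricted_mean_survival(km_low, horizon)
        >= restricted_mean_survival(km_high, horizon)
        else "above"
    )


def _fold_coefficients(X: np.ndarray, surv: SurvivalTable) -> np.ndarray:
    fits = cox_univariate_many(X, surv.time, surv.event)
    coefs = np.zeros(X.shape[1])
    bad = []
    for j, f in enumerate(fits):
        if f.converged:
            coefs[j] = f.coef
        else:
            bad.append(j)
    if bad:
        logger.warning(
            "%d of %d site fits unconverged (columns %s); coefficients set to 0",
            len(bad), X.shape[1], bad,
        )
    return coefs


def _prepare(matrix: MethylationMatrix, sites: Sequence[int]):
    sub = matrix.subset(sites)
    return sub.proportions.to_numpy(dtype=float), list(sub.proportions.index)


def _class_split_logrank(classes, surv: SurvivalTable) -> tuple[float, float]:
    keep = np.array([c is not None for c in classes])
    good = np.array([c == "good" for c in classes])[keep]
    sub = surv.mask(keep)
    if good.all() or not good.any():
        return 0.0, 1.0
    from .survival import _logrank_scan_core  # single-split reuse

    chi2, _, _ = _logrank_scan_core(sub.time, sub.event, good[None, :])
    return float(chi2[0]), float(stats.chi2.sf(chi2[0], 1))


def loocv(
    matrix: MethylationMatrix,
    surv_pfs: SurvivalTable,
    surv_os: SurvivalTable | None,
    sites: Sequence[int],
    min_group: int = 1,
) -> LOOCVResult:
    """Leave-one-out cross-validation of the M-score procedure.

    Every fold refits the per-site PFS Cox weights, reselects the threshold
    and relearns the good-side orientation on the n-1 remaining samples; the
    held-out sample is then scored and classified.  The predicted classes are
    finally compared by log-rank against each supplied endpoint.  Folds where
    threshold selection degenerates leave their sample unclassified (reported,
    never silently dropped).
    """
    X, ids = _prepare(matrix, sites)
    n = len(ids)
    if n < 10:
        raise ValueError("LOOCV needs at least 10 samples")
    pfs = surv_pfs.align(ids)
    os_tab = surv_os.align(ids) if surv_os is not None else None

    classes: list[str | None] = []
    sides: list[str | None] = []
    thresholds = np.full(n, np.nan)
    held_scores = np.full(n, np.nan)
    for i in range(n):
        rest = np.ones(n, dtype=bool)
        rest[i] = False
        Xtr = X[rest]
        means = np.nanmean(Xtr, axis=0)
        Xtr_filled = np.where(np.isnan(Xtr), means[None, :], Xtr)
        surv_tr = pfs.mask(rest)
        coefs = _fold_coefficients(Xtr_filled, surv_tr)
        train_scores = Xtr_filled @ coefs
        try:
            tau, _ = select_threshold(train_scores, surv_tr, min_group=min_group)
        except DegenerateScoresError:
            logger.warning("fold %s: degenerate threshold selection; unclassified", ids[i])
            classes.append(None)
            sides.append(None)
            continue
        side = _good_side(train_scores, tau, surv_tr)
        s_i = mscore(X[i], coefs, impute=means)
        thresholds[i] = tau
        sides.append(side)
        held_scores[i] = s_i
        if np.isnan(s_i):
            classes.append(None)
            continue
        low = s_i <= tau
        classes.append("good" if (side == "below") == low else "poor")

    by_endpoint = {"PFS": _class_split_logrank(classes, pfs)}
    if os_tab is not None:
        by_endpoint["OS"] = _class_split_logrank(classes, os_tab)
    return LOOCVResult(
        sample_ids=ids,
        classes=classes,
        fold_thresholds=thresholds,
        fold_good_sides=sides,
        scores=held_scores,
        logrank_by_endpoint=by_endpoint,
    )


def fit_final_model(
    matrix: MethylationMatrix,
    surv_pfs: SurvivalTable,
    sites: Sequence[int],
    loocv_result: LOOCVResult | None = None,
    min_group: int = 1,
) -> MScoreModel:
    """Train the deployable model on the full training cohort.

    Coefficients are the full-cohort univariate PFS Cox fits; the threshold is
    the arithmetic mean of the (non-degenerate) LOOCV fold thresholds; the
    orientation is the majority good-side across folds (full-cohort
    orientation on a tie).
    """
    X, ids = _prepare(matrix, sites)
    pfs = surv_pfs.align(ids)
    if loocv_result is None:
        loocv_result = loocv(matrix, surv_pfs, None, sites, min_group=min_group)
    means = np.nanmean(X, axis=0)
    X_filled = np.where(np.isnan(X), means[None, :], X)
    coefs = _fold_coefficients(X_filled, pfs)
    fold_taus = loocv_result.fold_thresholds
    valid = ~np.isnan(fold_taus)
    if not valid.any():
        raise DegenerateScoresError("no fold produced a threshold")
    tau = float(fold_taus[valid].mean())
    n_below = sum(s == "below" for s in loocv_result.fold_good_sides)
    n_above = sum(s == "above" for s in loocv_result.fold_good_sides)
    if n_below != n_above:
        side = "below" if n_below > n_above else "above"
    else:
        side = _good_side(X_filled @ coefs, tau, pfs)
    return MScoreModel(
        sites=tuple(int(s) for s in sites),
        coefficients=coefs,
        threshold=tau,
        good_side=side,
        endpoint=pfs.endpoint or "PFS",
        training_means=means,
        provenance={
            "n_training_samples": len(ids),
            "n_loocv_folds": int(valid.sum()),
        },
    )


def classify(model: MScoreModel, matrix: MethylationMatrix) -> dict[str, str | None]:
    """Classify samples as good/poor prognosis with a trained model.

    A score exactly at the threshold falls on the ``<=`` side, consistent with
    threshold selection.  Unscorable samples (too many missing subset sites)
    map to None.
    """
    sub = matrix.subset(list(model.sites))
    X = sub.proportions.to_numpy(dtype=float)
    out: dict[str, str | None] = {}
    for sid, row in zip(sub.proportions.index, X):
        s = mscore(row, model.coefficients, impute=model.training_means)
        if np.isnan(s):
            logger.warning("sample %s unscorable (missing subset sites)", sid)
            out[str(sid)] = None
            continue
        low = s <= model.threshold
        out[str(sid)] = "good" if (model.good_side == "below") == low else "poor"
    return out


def evaluate_split(
    classes: dict[str, str | None], surv: SurvivalTable
) -> tuple[float, float]:
    """Log-rank chi2/p of a good-vs-poor classification against an endpoint."""
    ids = [s for s in surv.sample_ids if classes.get(s) is not None]
    sub = surv.align(ids)
    labels = [classes[s] for s in ids]
    return _class_split_logrank(labels, sub)
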