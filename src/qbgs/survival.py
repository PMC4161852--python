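"""Survival primitives: univariate Cox fits, Kaplan-Meier, log-rank, screening.

The screening statistic throughout is the Cox *score test* at beta = 0 with
Breslow tie handling — for a grouped covariate this is exactly the classical
log-rank test, which is why per-site "log-rank p values" from a
continuous-covariate Cox model are well defined.  All fitting is implemented
as a Newton iteration on the Breslow partial likelihood, vectorised across
covariate columns so that thousands of univariate fits (77 sites x LOOCV
folds x simulation replicates) stay cheap.

Conventions: time is in months and strictly positive; event = 1 means the
endpoint (death / progression) was observed, 0 means censored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SurvivalTable",
    "CoxFit",
    "KaplanMeierCurve",
    "SiteScreenResult",
    "fit_cox_univariate",
    "cox_univariate_many",
    "kaplan_meier",
    "logrank",
    "logrank_scan",
    "screen_sites",
]

_MAX_ABS_BETA = 20.0  # monotone-likelihood cap (hazard ratio e^20 per unit)


@dataclass
class SurvivalTable:
    """Per-sample time-to-event records for one endpoint (OS or PFS)."""

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray
    endpoint: str = "OS"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=np.int8)
        n = len(self.sample_ids)
        if self.time.shape != (n,) or self.event.shape != (n,):
            raise ValueError("time/event length must match sample_ids")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample ids must be unique")
        if np.any(self.time <= 0):
            raise ValueError("survival times must be positive")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event indicators must be 0 or 1")

    def __len__(self) -> int:
        return len(self.sample_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, time_col: str, event_col: str,
                       id_col: str = "sample_id", endpoint: str = "OS"):
        return cls(
            sample_ids=[str(s) for s in df[id_col]],
            time=df[time_col].to_numpy(dtype=float),
            event=df[event_col].to_numpy(),
            endpoint=endpoint,
        )

    @classmethod
    def from_csv(cls, path, time_col: str, event_col: str,
                 id_col: str = "sample_id", endpoint: str = "OS"):
        return cls.from_dataframe(pd.read_csv(path), time_col, event_col, id_col, endpoint)

    @classmethod
    def from_sample_sheet(cls, path, endpoint: str, id_col: str = "sample_id"):
        """Read one endpoint from a combined sample sheet.

        Expects columns ``os_time_months, os_event, pfs_time_months,
        pfs_event`` (endpoint = "OS" or "PFS").
        """
        prefix = endpoint.lower()
        return cls.from_csv(
            path, f"{prefix}_time_months", f"{prefix}_event", id_col, endpoint.upper()
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "time_months": self.time,
                "event": self.event,
            }
        ).to_csv(path, index=False)

    def align(self, sample_ids: Sequence[str]) -> "SurvivalTable":
        """Reorder/subset to the given sample ids (all must be present)."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            idx = np.array([index[str(s)] for s in sample_ids])
        except KeyError as e:
            raise KeyError(f"sample {e} missing from survival table") from None
        return SurvivalTable(
            [str(s) for s in sample_ids], self.time[idx], self.event[idx], self.endpoint
        )

    def mask(self, keep: np.ndarray) -> "SurvivalTable":
        keep = np.asarray(keep, dtype=bool)
        ids = [s for s, k in zip(self.sample_ids, keep) if k]
        return SurvivalTable(ids, self.time[keep], self.event[keep], self.endpoint)


@dataclass
class CoxFit:
    """A univariate Cox proportional-hazards fit (Breslow ties)."""

    coef: float
    se: float
    score_chi2: float
    score_p: float
    wald_p: float
    converged: bool
    n_used: int
    flag: str = ""


@dataclass
class KaplanMeierCurve:
    """Product-limit estimate: S(t) evaluated at the distinct event times."""

    times: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray

    def survival_at(self, t: float) -> float:
        """Right-continuous step-function lookup; S(t) = 1 before any event."""
        k = np.searchsorted(self.times, t, side="right")
        return 1.0 if k == 0 else float(self.survival[k - 1])

    @property
    def median(self) -> float:
        """Smallest event time with S(t) <= 0.5, or +inf if never reached."""
        below = np.nonzero(self.survival <= 0.5)[0]
        return float(self.times[below[0]]) if below.size else float("inf")


@dataclass
class SiteScreenResult:
    """Per-site univariate Cox screen, ordered by ascending p."""

    table: pd.DataFrame  # columns: label, coef, p, selected
    alpha: float
    excluded_labels: list[int] = field(default_factory=list)

    @property
    def selected(self) -> list[int]:
        return [int(l) for l in self.table.loc[self.table["selected"], "label"]]

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out["label"] = [f"CpG{l}" for l in out["label"]]
        out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Breslow partial-likelihood machinery (vectorised over covariate columns)
# ---------------------------------------------------------------------------


def _risk_structure(time: np.ndarray, event: np.ndarray):
    """Sort descending by time and precompute tie-block bookkeeping."""
    order = np.argsort(-time, kind="stable")
    t_s, e_s = time[order], event[order]
    new_block = np.r_[True, t_s[1:] != t_s[:-1]]
    block_id = np.cumsum(new_block) - 1
    # last row index of each tie block, in descending-time order
    block_last = np.r_[np.nonzero(new_block)[0][1:] - 1, len(t_s) - 1]
    return order, t_s, e_s.astype(bool), block_id, block_last


def _breslow_quantities(X_s, e_s, block_id, block_last, beta):
    """Log partial likelihood, score and information per column."""
    eta = X_s * beta[None, :]
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    S0 = np.cumsum(w, axis=0)[block_last][block_id]
    S1 = np.cumsum(X_s * w, axis=0)[block_last][block_id]
    S2 = np.cumsum(X_s * X_s * w, axis=0)[block_last][block_id]
    Xe, S0e, S1e, S2e = X_s[e_s], S0[e_s], S1[e_s], S2[e_s]
    ll = np.sum(Xe * beta[None, :] - np.log(S0e), axis=0)
    r1 = S1e / S0e
    U = np.sum(Xe - r1, axis=0)
    I = np.sum(S2e / S0e - r1 * r1, axis=0)
    return ll, U, I


def cox_univariate_many(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-9,
) -> list[CoxFit]:
    """Fit one univariate Cox model per column of ``X`` (no missing values).

    Newton iteration with step-halving on the Breslow log partial likelihood;
    degenerate columns (no events, constant covariate) are returned
    unconverged with p = 1, and monotone-likelihood divergence is flagged with
    the coefficient capped.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (samples x covariates)")
    n, p = X.shape
    order, t_s, e_s, block_id, block_last = _risk_structure(
        np.asarray(time, float), np.asarray(event)
    )
    X_s = X[order]
    beta = np.zeros(p)
    ll0, U0, I0 = _breslow_quantities(X_s, e_s, block_id, block_last, beta)
    # a constant covariate yields information 0 only up to rounding noise
    col_range = X.max(axis=0) - X.min(axis=0)
    info_floor = 64 * n * np.finfo(float).eps * np.maximum(col_range, 1.0) ** 2
    informative = (col_range > 0) & (I0 > info_floor)
    with np.errstate(divide="ignore", invalid="ignore"):
        score_chi2 = np.where(informative, U0 * U0 / I0, 0.0)
    score_p = np.where(informative, stats.chi2.sf(score_chi2, 1), 1.0)
    degenerate = ~informative | (e_s.sum() == 0)

    ll = ll0.copy()
    converged = np.zeros(p, dtype=bool)
    capped = np.zeros(p, dtype=bool)
    for _ in range(max_iter):
        active = ~(converged | degenerate | capped)
        if not active.any():
            break
        _, U, I = _breslow_quantities(X_s, e_s, block_id, block_last, beta)
        step = np.zeros(p)
        good = active & (I > 0)
        step[good] = U[good] / I[good]
        cand = beta + step
        ll_new, _, _ = _breslow_quantities(X_s, e_s, block_id, block_last, cand)
        # step-halving where the likelihood decreased
        for _h in range(30):
            worse = active & (ll_new < ll - 1e-12)
            if not worse.any():
                break
            step[worse] *= 0.5
            cand = beta + step
            ll_new, _, _ = _breslow_quantities(X_s, e_s, block_id, block_last, cand)
        newly_conv = active & (np.abs(ll_new - ll) < tol)
        beta = np.where(active, cand, beta)
        ll = np.where(active, ll_new, ll)
        converged |= newly_conv
        over = np.abs(beta) > _MAX_ABS_BETA
        capped |= active & over
        beta = np.clip(beta, -_MAX_ABS_BETA, _MAX_ABS_BETA)

    _, _, I_hat = _breslow_quantities(X_s, e_s, block_id, block_last, beta)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.where(I_hat > 0, 1.0 / np.sqrt(np.maximum(I_hat, 1e-300)), np.nan)
        wald = np.where(I_hat > 0, stats.chi2.sf((beta / se) ** 2, 1), 1.0)
    fits = []
    for j in range(p):
        if degenerate[j]:
            fits.append(
                CoxFit(np.nan, np.nan, 0.0, 1.0, 1.0, False, n, flag="degenerate")
            )
        else:
            fits.append(
                CoxFit(
                    coef=float(beta[j]),
                    se=float(se[j]),
                    score_chi2=float(score_chi2[j]),
                    score_p=float(score_p[j]),
                    wald_p=float(wald[j]),
                    converged=bool(converged[j] and not capped[j]),
                    n_used=n,
                    flag="monotone_likelihood" if capped[j] else "",
                )
            )
    return fits


def fit_cox_univariate(x: np.ndarray, surv: SurvivalTable, **kwargs) -> CoxFit:
    """Univariate Cox fit of one covariate; samples with missing x are dropped."""
    x = np.asarray(x, dtype=float)
    keep = ~np.isnan(x)
    fit = cox_univariate_many(
        x[keep, None], surv.time[keep], surv.event[keep], **kwargs
    )[0]
    fit.n_used = int(keep.sum())
    return fit


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------


def kaplan_meier(surv: SurvivalTable) -> KaplanMeierCurve:
    """Product-limit estimator.

    Samples censored at an event time remain at risk through that time (the
    standard convention); S is evaluated at the distinct observed event times.
    """
    if len(surv) == 0:
        raise ValueError("empty survival table")
    time, event = surv.time, surv.event.astype(bool)
    ev_times = np.unique(time[event])
    at_risk = np.array([(time >= t).sum() for t in ev_times], dtype=np.int64)
    d = np.array([(event & (time == t)).sum() for t in ev_times], dtype=np.int64)
    surv_fn = np.cumprod(1.0 - d / at_risk) if ev_times.size else np.array([])
    return KaplanMeierCurve(ev_times, at_risk, d, surv_fn)


def restricted_mean_survival(curve: KaplanMeierCurve, horizon: float) -> float:
    """Area under the KM step function on [0, horizon]."""
    t_prev, s_prev, area = 0.0, 1.0, 0.0
    for t, s in zip(curve.times, curve.survival):
        if t >= horizon:
            break
        area += s_prev * (t - t_prev)
        t_prev, s_prev = float(t), float(s)
    area += s_prev * (horizon - t_prev)
    return area


def logrank(surv_a: SurvivalTable, surv_b: SurvivalTable) -> tuple[float, float]:
    """Two-group log-rank test (1 df), hypergeometric variance with ties.

    Returns ``(chi2, p)``; two groups with no events at all give (0, 1).
    """
    if len(surv_a) == 0 or len(surv_b) == 0:
        raise ValueError("both groups must be non-empty")
    time = np.r_[surv_a.time, surv_b.time]
    event = np.r_[surv_a.event, surv_b.event]
    group = np.r_[np.ones(len(surv_a), bool), np.zeros(len(surv_b), bool)]
    chi2s, _, _ = _logrank_scan_core(time, event, group[None, :])
    chi2 = float(chi2s[0])
    return chi2, float(stats.chi2.sf(chi2, 1))


def _logrank_scan_core(time, event, membership):
    """Log-rank chi-square for each row of a membership matrix.

    ``membership`` is (n_candidates x n_samples) boolean: True = group 1.
    Returns (chi2, observed-minus-expected, variance) arrays.
    """
    time = np.asarray(time, float)
    event = np.asarray(event).astype(bool)
    order = np.argsort(time, kind="stable")
    t_s, e_s = time[order], event[order]
    memb = membership[:, order]  # C x n
    n = len(t_s)
    starts = np.r_[0, 1 + np.nonzero(t_s[1:] != t_s[:-1])[0]]
    # totals per distinct time
    d_k = np.add.reduceat(e_s.astype(np.int64), starts)
    n_k = n - starts  # at risk = everyone with time >= t_k
    # group-1 at risk: suffix sums of membership, taken at block starts
    suffix = np.cumsum(memb[:, ::-1], axis=1)[:, ::-1]
    n1_k = suffix[:, starts].astype(float)
    d1_k = np.add.reduceat(memb & e_s[None, :], starts, axis=1).astype(float)
    has_events = d_k > 0
    frac = n1_k[:, has_events] / n_k[has_events]
    dk = d_k[has_events]
    nk = n_k[has_events]
    OE = np.sum(d1_k[:, has_events] - dk * frac, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        var_terms = dk * frac * (1.0 - frac) * np.where(nk > 1, (nk - dk) / (nk - 1.0), 0.0)
    V = np.sum(var_terms, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(V > 0, OE * OE / V, 0.0)
    return chi2, OE, V


def logrank_scan(
    scores: np.ndarray,
    surv: SurvivalTable,
    min_group: int = 1,
):
    """Log-rank chi2/p for every admissible split ``score <= tau`` vs ``> tau``.

    Candidates are the observed score values; candidates leaving fewer than
    ``min_group`` samples on either side are skipped.  Returns
    ``(candidates, chi2, p)`` arrays (possibly empty).
    """
    scores = np.asarray(scores, float)
    uniq = np.unique(scores)
    counts = np.searchsorted(np.sort(scores), uniq, side="right")
    n = len(scores)
    admissible = (counts >= min_group) & (n - counts >= min_group)
    cands = uniq[admissible]
    if cands.size == 0:
        return cands, np.array([]), np.array([])
    membership = scores[None, :] <= cands[:, None]
    chi2, _, _ = _logrank_scan_core(surv.time, surv.event, membership)
    p = stats.chi2.sf(chi2, 1)
    p = np.where(chi2 > 0, p, 1.0)
    return cands, chi2, p


def screen_sites(
    matrix,
    surv: SurvivalTable,
    alpha: float = 0.05,
) -> SiteScreenResult:
    """Univariate Cox screen of every analyzed site against one endpoint.

    Sites are ranked by the score-test p (the log-rank generalisation); the
    selected set is {p < alpha}, deliberately with no multiple-testing
    correction.  All-missing sites are excluded and reported.
    """
    surv = surv.align(matrix.sample_ids)
    props = matrix.proportions
    labels = list(props.columns)
    X = props.to_numpy(dtype=float)
    excluded = [int(l) for l, col in zip(labels, X.T) if np.isnan(col).all()]
    rows = []
    clean = ~np.isnan(X).any()
    if clean:
        fits = cox_univariate_many(X, surv.time, surv.event)
        for l, f in zip(labels, fits):
            rows.append((int(l), f.coef, f.score_p))
    else:
        for l, col in zip(labels, X.T):
            if int(l) in excluded:
                continue
            f = fit_cox_univariate(col, surv)
            rows.append((int(l), f.coef, f.score_p))
    table = pd.DataFrame(rows, columns=["label", "coef", "p"])
    table = table.sort_values("p", kind="stable", ignore_index=True)
    table["selected"] = table["p"] < alpha
    return SiteScreenResult(table=table, alpha=alpha, excluded_labels=excluded)
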