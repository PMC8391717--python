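"""Native survival statistics: product-limit and cumulative-hazard estimators,
the multi-group Mantel-Cox log-rank test, Cox proportional-hazards regression
with the Efron tie correction, and Harrell's concordance index.

Conventions
-----------
* At a tied instant, events precede censorings: both are counted at risk at
  that time, and censored subjects leave the risk set just after it.
* ``events`` vectors are 0 (censored) / 1 (death).
* Risk scores passed to :func:`concordance_index` are oriented so that a
  higher score means shorter predicted survival.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "SurvivalCurve",
    "CumulativeHazardCurve",
    "LogRankResult",
    "CoxFit",
    "km_estimate",
    "na_cumhaz",
    "log_rank",
    "cox_fit",
    "concordance_index",
]

_Z95 = 1.959963984540054


def _event_table(times, events):
    """Unique event times with event counts and at-risk counts."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty input")
    if times.ndim != 1 or times.shape != events.shape:
        raise ValueError("times and events must be equal-length 1-d vectors")
    if (times < 0).any():
        raise ValueError("negative survival times")
    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order]
    uniq, inverse = np.unique(t[e == 1], return_inverse=True)
    d = np.bincount(inverse, minlength=uniq.size)
    n = t.size - np.searchsorted(t, uniq, side="left")
    return uniq, d.astype(int), n.astype(int)


@dataclass
class SurvivalCurve:
    """Step-function product-limit estimate with Greenwood variance and
    log(-log) 95% confidence bands."""

    event_times: np.ndarray
    survival: np.ndarray
    greenwood_variance: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray

    def at(self, t: float) -> float:
        """Step lookup: the estimate just after time ``t``."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "survival": self.survival,
                "variance": self.greenwood_variance,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "n_at_risk": self.n_at_risk,
                "n_events": self.n_events,
            }
        )


@dataclass
class CumulativeHazardCurve:
    event_times: np.ndarray
    cumhaz: np.ndarray
    variance: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray

    def at(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 0.0 if idx < 0 else float(self.cumhaz[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "cumhaz": self.cumhaz,
                "variance": self.variance,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "n_at_risk": self.n_at_risk,
                "n_events": self.n_events,
            }
        )


def km_estimate(times, events) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimate.

    Greenwood's formula supplies the variance; the 95% confidence band uses
    the log(-log) transform so bounds stay inside [0, 1].
    """
    t, d, n = _event_table(times, events)
    if t.size == 0:
        logger.warning("no events observed; survival curve is flat at 1")
        return SurvivalCurve(
            np.array([]), np.array([]), np.array([]), np.array([]), np.array([]),
            np.array([], dtype=int), np.array([], dtype=int),
        )
    s = np.cumprod(1.0 - d / n)
    with np.errstate(divide="ignore"):
        terms = np.where(n > d, d / (n * np.clip(n - d, 1, None)), np.inf)
    gw_sum = np.cumsum(terms)
    # once S hits 0 the Greenwood product is 0 by convention
    var = np.where(s > 0, s**2 * np.where(np.isfinite(gw_sum), gw_sum, 0.0), 0.0)
    lo = np.zeros_like(s)
    hi = np.zeros_like(s)
    with np.errstate(divide="ignore", invalid="ignore"):
        for i, (si, g) in enumerate(zip(s, gw_sum)):
            if si <= 0.0 or si >= 1.0 or not np.isfinite(g):
                lo[i], hi[i] = (0.0, 0.0) if si <= 0 else (si, si)
                continue
            theta_se = np.sqrt(g) / abs(np.log(si))
            lo[i] = si ** np.exp(_Z95 * theta_se)
            hi[i] = si ** np.exp(-_Z95 * theta_se)
    return SurvivalCurve(t, s, var, lo, hi, n, d)


def na_cumhaz(times, events) -> CumulativeHazardCurve:
    """Nelson-Aalen cumulative hazard with the Aalen variance estimate."""
    t, d, n = _event_table(times, events)
    if t.size == 0:
        return CumulativeHazardCurve(
            np.array([]), np.array([]), np.array([]), np.array([]), np.array([]),
            np.array([], dtype=int), np.array([], dtype=int),
        )
    h = np.cumsum(d / n)
    var = np.cumsum(d / n**2)
    se = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(h > 0, np.exp(_Z95 * se / np.where(h > 0, h, 1.0)), 1.0)
    lo = h / ratio
    hi = h * ratio
    return CumulativeHazardCurve(t, h, var, lo, hi, n, d)


@dataclass
class LogRankResult:
    chi_square: float
    df: int
    p_value: float


def log_rank(groups: Sequence[tuple]) -> LogRankResult:
    """Mantel-Cox log-rank test across two or more groups.

    ``groups`` is a sequence of ``(times, events)`` pairs.  The statistic uses
    the hypergeometric covariance of the per-time event allocations;
    df = k - 1.
    """
    if len(groups) < 2:
        raise ValueError("log-rank needs at least two groups")
    times = [np.asarray(t, dtype=float) for t, _ in groups]
    events = [np.asarray(e, dtype=int) for _, e in groups]
    if any(t.size == 0 for t in times):
        raise ValueError("log-rank groups must be non-empty")
    k = len(groups)
    all_t = np.concatenate(times)
    all_e = np.concatenate(events)
    uniq = np.unique(all_t[all_e == 1])
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for u in uniq:
        n_g = np.array([float((t >= u).sum()) for t in times])
        d_g = np.array([float(((t == u) & (e == 1)).sum()) for t, e in zip(times, events)])
        n = n_g.sum()
        d = d_g.sum()
        O += d_g
        E += d * n_g / n
        if n > 1:
            frac = n_g / n
            c = d * (n - d) / (n - 1)
            V += c * (np.diag(frac) - np.outer(frac, frac))
    z = (O - E)[:-1]
    Vr = V[:-1, :-1]
    try:
        chi2 = float(z @ np.linalg.solve(Vr, z))
    except np.linalg.LinAlgError:
        chi2 = float(z @ np.linalg.pinv(Vr) @ z)
    chi2 = max(chi2, 0.0)
    df = k - 1
    p = float(stats.chi2.sf(chi2, df))
    return LogRankResult(chi2, df, p)


@dataclass
class CoxFit:
    """Fitted proportional-hazards model with Wald inference."""

    summary: pd.DataFrame  # coef, se, hazard_ratio, ci_low, ci_high, p_value per row
    log_likelihood: float
    iterations: int
    converged: bool
    ties_method: str = "efron"

    @property
    def coefficients(self) -> pd.Series:
        return self.summary["coef"]

    @property
    def hazard_ratios(self) -> pd.Series:
        return self.summary["hazard_ratio"]

    def forest_table(self) -> pd.DataFrame:
        """HR with 95% CI and p-value per covariate, forest-plot layout."""
        t = self.summary[["hazard_ratio", "ci_low", "ci_high", "p_value"]].copy()
        t.columns = ["HR", "CI95_low", "CI95_high", "p"]
        return t


def _design_matrix(data: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    """Numeric design matrix; categorical columns one-hot expanded against the
    first observed level as reference."""
    cols = {}
    for cov in covariates:
        col = data[cov]
        if pd.api.types.is_numeric_dtype(col):
            cols[cov] = col.astype(float).to_numpy()
        else:
            levels = list(pd.unique(col))
            for lev in levels[1:]:
                cols[f"{cov}[{lev}]"] = (col == lev).astype(float).to_numpy()
    return pd.DataFrame(cols, index=data.index)


def efron_log_likelihood(beta, X, times, events, time_interaction_idx=None):
    """Efron partial log-likelihood (direct risk-set evaluation).

    Exposed separately so the optimizer can be cross-checked against this
    definition; also used as the brute-force oracle path in the test suite.
    """
    beta = np.asarray(beta, dtype=float)
    X = np.asarray(X, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    ll = 0.0
    for u in np.unique(times[events == 1]):
        risk = times >= u
        dead = (times == u) & (events == 1)
        Xu = X
        if time_interaction_idx:
            extra = X[:, time_interaction_idx] * np.log(max(u, 1e-12))
            Xu = np.hstack([X, extra])
        eta = Xu @ beta
        w = np.exp(eta)
        d = int(dead.sum())
        s0 = w[risk].sum()
        s0_d = w[dead].sum()
        ll += eta[dead].sum()
        for l in range(d):
            ll -= np.log(s0 - (l / d) * s0_d)
    return float(ll)


def cox_fit(
    data,
    covariates: Sequence[str],
    duration_col: str = "os_months",
    event_col: str = "os_event",
    ties: str = "efron",
    time_interaction: Sequence[str] | None = None,
    max_iter: int = 50,
    tol: float = 1e-9,
) -> CoxFit:
    """Fit a Cox proportional-hazards model by Newton-Raphson maximization of
    the Efron partial likelihood.

    ``data`` is a DataFrame (or anything with a ``.data`` DataFrame attribute);
    categorical covariates are one-hot expanded.  ``time_interaction`` names
    covariates that additionally enter as ``x * log(t)`` terms, the standard
    diagnostic for a time-dependent (non-proportional) effect — a significant
    Wald p on the interaction term flags a violation.

    Non-convergence and monotone-likelihood (separation) situations are
    reported on the returned fit rather than raised.
    """
    if ties != "efron":
        raise ValueError("only the Efron tie correction is implemented")
    df = getattr(data, "data", data)
    design = _design_matrix(df, covariates)
    base_names = list(design.columns)
    X = design.to_numpy(dtype=float)
    times = df[duration_col].to_numpy(dtype=float)
    events = df[event_col].to_numpy(dtype=int)
    if events.sum() < 1:
        raise ValueError("Cox regression needs at least one event")
    if design.shape[1] == 0:
        raise ValueError(
            "no usable covariates (all requested columns are constant)"
        )

    ti_idx = None
    names = list(base_names)
    if time_interaction:
        ti_idx = [base_names.index(c) for c in base_names if any(c.startswith(v) for v in time_interaction)]
        names += [f"{base_names[i]}:log(t)" for i in ti_idx]

    center = X.mean(axis=0)
    Xc = X - center
    p = len(names)
    beta = np.zeros(p)

    uniq = np.unique(times[events == 1])
    # per-event-time caches
    risk_masks = [times >= u for u in uniq]
    dead_masks = [(times == u) & (events == 1) for u in uniq]
    if ti_idx is not None:
        designs = [np.hstack([Xc, Xc[:, ti_idx] * np.log(max(u, 1e-12))]) for u in uniq]
    else:
        designs = [Xc] * len(uniq)

    def loglik_grad_hess(b):
        ll = 0.0
        g = np.zeros(p)
        H = np.zeros((p, p))
        for risk, dead, Xu in zip(risk_masks, dead_masks, designs):
            eta = Xu @ b
            w = np.exp(np.clip(eta, -500, 500))
            d = int(dead.sum())
            Xr, wr = Xu[risk], w[risk]
            s0 = wr.sum()
            s1 = wr @ Xr
            s2 = (wr[:, None] * Xr).T @ Xr
            Xd, wd = Xu[dead], w[dead]
            s0d = wd.sum()
            s1d = wd @ Xd
            s2d = (wd[:, None] * Xd).T @ Xd
            ll += eta[dead].sum()
            g += Xd.sum(axis=0)
            for l in range(d):
                f = l / d
                a0 = s0 - f * s0d
                a1 = s1 - f * s1d
                a2 = s2 - f * s2d
                z = a1 / a0
                ll -= np.log(a0)
                g -= z
                H -= a2 / a0 - np.outer(z, z)
        return ll, g, H

    ll, g, H = loglik_grad_hess(beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(-H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.solve(-H + 1e-8 * np.eye(p), g)
        # step-halving line search
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new, g_new, H_new = loglik_grad_hess(cand)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        beta, ll, g, H = cand, ll_new, g_new, H_new
        if np.max(np.abs(scale * step)) < tol:
            converged = True
            break
    if not converged:
        logger.warning("Cox fit did not converge in %d iterations", max_iter)
    if np.any(np.abs(beta) > 15):
        logger.warning(
            "very large coefficient(s) %s: possible monotone likelihood / separation",
            np.round(beta, 2),
        )

    try:
        cov = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        cov = np.linalg.inv(-H + 1e-8 * np.eye(p))
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        zstat = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pvals = 2.0 * stats.norm.sf(np.abs(zstat))
    with np.errstate(over="ignore"):
        summary = pd.DataFrame(
            {
                "coef": beta,
                "se": se,
                "hazard_ratio": np.exp(beta),
                "ci_low": np.exp(beta - _Z95 * se),
                "ci_high": np.exp(np.minimum(beta + _Z95 * se, 709.0)),
                "p_value": pvals,
            },
            index=names,
        )
    return CoxFit(summary, float(ll), it, converged, ties)


def concordance_index(risk_scores, times, events) -> float:
    """Harrell's C over usable pairs.

    A pair is usable when the shorter time belongs to a subject with an
    observed event; a tied risk prediction scores 1/2.  Higher risk must mean
    shorter predicted survival.
    """
    r = np.asarray(risk_scores, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if r.shape != t.shape or t.shape != e.shape:
        raise ValueError("inputs must share a common length")
    conc = 0.0
    usable = 0
    for i in np.flatnonzero(e == 1):
        later = t > t[i]
        if not later.any():
            continue
        usable += int(later.sum())
        conc += float((r[i] > r[later]).sum()) + 0.5 * float((r[i] == r[later]).sum())
    if usable == 0:
        raise ValueError("no usable pairs: cannot compute a concordance index")
    return conc / usable
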