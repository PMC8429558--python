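"""Native survival inference: Kaplan-Meier, log-rank, Cox proportional hazards.

These are deliberately self-contained implementations (numpy only) of the
three classical right-censored survival tools the stratified prognostic
analyses rest on:

* the product-limit (Kaplan-Meier) survival estimator, events-before-
  censorings at tied times;
* the k-sample log-rank test with the hypergeometric variance and the
  standard multi-event tie formula;
* a Cox proportional-hazards model maximising the Efron partial likelihood
  by Newton-Raphson, with Wald standard errors, 95 % CIs and p-values.

lifelines is used in the test suite as an independent oracle, never here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from sklearn.base import BaseEstimator

__all__ = [
    "KMCurve",
    "LogRankResult",
    "CoxFit",
    "KaplanMeier",
    "CoxPH",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "survival_from",
    "ConvergenceWarning",
]


class ConvergenceWarning(UserWarning):
    """Raised-as-warning when a partial-likelihood fit is suspect."""


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate: S(t) at each distinct event time."""

    event_times: np.ndarray   # distinct times with >= 1 event, ascending
    survival: np.ndarray      # S(t) just after each event time
    at_risk: np.ndarray       # risk-set size just before each event time
    events: np.ndarray        # events at each event time
    median_survival: float    # smallest t with S(t) <= 0.5, NaN if never

    def survival_at(self, t: float) -> float:
        """Step-function value S(t); S = 1 before the first event."""
        idx = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.event_times,
            "survival": self.survival,
            "at_risk": self.at_risk,
            "events": self.events,
        })


def _clean_samples(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    if time.size == 0:
        raise ValueError("need at least one survival sample")
    if time.shape != event.shape:
        raise ValueError("time and event must have equal length")
    if np.any(~np.isfinite(time)) or np.any(time <= 0):
        raise ValueError("survival times must be positive and finite")
    return time, event


def km_estimate(time, event) -> KMCurve:
    """Kaplan-Meier estimate from times (months) and event indicators.

    At tied times events are processed before censorings, i.e. subjects
    censored at t remain in the risk set for events at t.
    """
    time, event = _clean_samples(time, event)
    n = time.size
    order = np.argsort(time, kind="stable")
    t_sorted, e_sorted = time[order], event[order]

    ev_times = np.unique(t_sorted[e_sorted])
    at_risk = np.empty(ev_times.size, dtype=int)
    d = np.empty(ev_times.size, dtype=int)
    surv = np.empty(ev_times.size, dtype=float)
    s = 1.0
    for i, t in enumerate(ev_times):
        # censorings at exactly t have not yet left the risk set
        at_risk[i] = int(np.sum(t_sorted >= t))
        d[i] = int(np.sum(e_sorted & (t_sorted == t)))
        s *= 1.0 - d[i] / at_risk[i]
        surv[i] = s

    below = np.nonzero(surv <= 0.5)[0]
    median = float(ev_times[below[0]]) if below.size else float("nan")
    return KMCurve(ev_times, surv, at_risk, d, median)


class KaplanMeier(BaseEstimator):
    """Estimator wrapper around :func:`km_estimate`.

    ``fit(time, event)`` stores the curve as ``curve_``;
    ``predict(times)`` evaluates the fitted step function.
    """

    def fit(self, time, event) -> "KaplanMeier":
        self.curve_ = km_estimate(time, event)
        self.median_survival_ = self.curve_.median_survival
        return self

    def predict(self, times) -> np.ndarray:
        return np.array([self.curve_.survival_at(t) for t in np.atleast_1d(times)])


# ---------------------------------------------------------------------------
# Log-rank test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LogRankResult:
    statistic: float
    df: int
    p: float


def logrank_test(times_by_group, events_by_group) -> LogRankResult:
    """k-sample log-rank test over pooled event times.

    Parameters are sequences of per-group time and event arrays. The
    chi-square statistic uses the observed-minus-expected vector for the
    first k-1 groups and the hypergeometric covariance at each distinct
    event time (multi-event tie formula with the (N-d)/(N-1) factor).
    """
    k = len(times_by_group)
    if k < 2 or len(events_by_group) != k:
        raise ValueError("need >= 2 labelled groups")
    groups = [_clean_samples(t, e) for t, e in zip(times_by_group, events_by_group)]
    time = np.concatenate([t for t, _ in groups])
    event = np.concatenate([e for _, e in groups])
    grp = np.concatenate([np.full(t.size, g) for g, (t, _) in enumerate(groups)])
    if not event.any():
        raise ValueError("log-rank statistic undefined: no events in any group")

    ev_times = np.unique(time[event])
    omE = np.zeros(k - 1)
    V = np.zeros((k - 1, k - 1))
    for t in ev_times:
        at_risk = time >= t
        N = int(at_risk.sum())
        d = int((event & (time == t)).sum())
        if N <= 0 or d == 0:
            continue
        n_g = np.array([(at_risk & (grp == g)).sum() for g in range(k)], dtype=float)
        d_g = np.array([(event & (time == t) & (grp == g)).sum() for g in range(k)],
                       dtype=float)
        p_g = n_g / N
        omE += (d_g - d * p_g)[:-1]
        if N > 1:
            c = d * (N - d) / (N - 1)
            V += c * (np.diag(p_g[:-1]) - np.outer(p_g[:-1], p_g[:-1]))

    # pseudo-inverse guards degenerate layouts (e.g. a group with no overlap)
    stat = float(omE @ np.linalg.pinv(V) @ omE)
    stat = max(stat, 0.0)
    df = k - 1
    return LogRankResult(stat, df, float(stats.chi2.sf(stat, df)))


# ---------------------------------------------------------------------------
# Cox proportional hazards, Efron ties
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoxFit:
    """Fitted proportional-hazards model (one row per covariate)."""

    covariates: list
    coef: np.ndarray
    se: np.ndarray
    hazard_ratio: np.ndarray
    ci95_low: np.ndarray
    ci95_high: np.ndarray
    wald_p: np.ndarray
    log_likelihood: float
    iterations: int
    converged: bool
    flags: list = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "coef": self.coef,
            "se": self.se,
            "HR": self.hazard_ratio,
            "ci95_low": self.ci95_low,
            "ci95_high": self.ci95_high,
            "p": self.wald_p,
        }, index=pd.Index(self.covariates, name="covariate"))

    def to_dict(self) -> dict:
        d = {c: {"coef": float(b), "se": float(s), "HR": float(h),
                 "ci95_low": float(lo), "ci95_high": float(hi), "p": float(p)}
             for c, b, s, h, lo, hi, p in zip(
                 self.covariates, self.coef, self.se, self.hazard_ratio,
                 self.ci95_low, self.ci95_high, self.wald_p)}
        d["_model"] = {"log_likelihood": self.log_likelihood,
                       "iterations": self.iterations,
                       "converged": self.converged,
                       "flags": list(self.flags)}
        return d


def _efron_loglik_derivs(beta, X, time, event):
    """Efron partial log-likelihood with gradient and Hessian.

    Subjects sorted by time ascending; risk sets accumulated from the
    largest time downwards so each event time costs O(d x p^2).
    """
    n, p = X.shape
    eta = X @ beta
    eta -= eta.max()  # guard overflow; partial likelihood is shift-invariant
    w = np.exp(eta)

    order = np.argsort(time, kind="stable")[::-1]  # descending time
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    S0 = 0.0
    S1 = np.zeros(p)
    S2 = np.zeros((p, p))
    i = 0
    while i < n:
        t = time[order[i]]
        j = i
        block = []
        while j < n and time[order[j]] == t:
            idx = order[j]
            S0 += w[idx]
            S1 += w[idx] * X[idx]
            S2 += w[idx] * np.outer(X[idx], X[idx])
            if event[idx]:
                block.append(idx)
            j += 1
        d = len(block)
        if d:
            idxs = np.array(block)
            wD = w[idxs].sum()
            s1D = (w[idxs, None] * X[idxs]).sum(axis=0)
            s2D = np.einsum("i,ij,ik->jk", w[idxs], X[idxs], X[idxs])
            ll += eta[idxs].sum()
            grad += X[idxs].sum(axis=0)
            for l in range(d):
                f = l / d
                a0 = S0 - f * wD
                a1 = S1 - f * s1D
                a2 = S2 - f * s2D
                ll -= np.log(a0)
                grad -= a1 / a0
                hess -= a2 / a0 - np.outer(a1, a1) / a0**2
        i = j
    return ll, grad, hess


def cox_fit(X, time, event, covariates=None, *, tie_method: str = "efron",
            max_iter: int = 50, tol: float = 1e-9) -> CoxFit:
    """Cox proportional-hazards fit by Newton-Raphson.

    Parameters
    ----------
    X : (n, p) array or DataFrame
        Complete covariate matrix (rows with missing values must be dropped
        by the caller).
    time, event : arrays
        Right-censored survival data.
    tie_method : {"efron", "breslow"}
        Tie approximation for the partial likelihood. Breslow is obtained
        by treating every tied event as a separate block (f = 0), which the
        Efron routine reduces to when told d = 1 per event; implemented via
        jittering the internal tie grouping is avoided -- Breslow simply
        sets the Efron fractional weights to zero.

    Non-convergence is flagged, never silent; monotone-likelihood
    (complete separation) is reported through a diverging-coefficient flag
    and a :class:`ConvergenceWarning`.
    """
    if isinstance(X, pd.DataFrame):
        covariates = covariates or list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        covariates = covariates or [f"x{i}" for i in range(X.shape[1])]
    time, event = _clean_samples(time, event)
    if X.shape[0] != time.size:
        raise ValueError("covariate matrix and survival data disagree in length")
    if np.isnan(X).any():
        raise ValueError("covariate matrix contains missing values")
    if not event.any():
        raise ValueError("Cox model requires at least one event")
    if tie_method not in ("efron", "breslow"):
        raise ValueError(f"unknown tie method {tie_method!r}")

    n, p = X.shape
    flags: list[str] = []

    # centre covariates for numerical stability; beta is unaffected
    centre = X.mean(axis=0)
    Xc = X - centre
    sd = Xc.std(axis=0)
    if np.any(sd == 0):
        const = [covariates[i] for i in np.nonzero(sd == 0)[0]]
        flags.append(f"constant covariates (no information): {const}")
    if np.linalg.matrix_rank(Xc) < p:
        flags.append("rank-deficient design matrix")
        warnings.warn("covariate matrix is rank deficient; coefficients are "
                      "not identifiable", ConvergenceWarning, stacklevel=2)

    derivs = _efron_loglik_derivs if tie_method == "efron" else _breslow_loglik_derivs

    beta = np.zeros(p)
    ll, grad, hess = derivs(beta, Xc, time, event)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(-hess, grad, rcond=None)[0]
        # step-halving to keep the likelihood non-decreasing
        alpha = 1.0
        for _ in range(30):
            cand = beta + alpha * step
            ll_new, grad_new, hess_new = derivs(cand, Xc, time, event)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            alpha /= 2.0
        delta = np.max(np.abs(cand - beta))
        beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
        if np.max(np.abs(grad)) < tol or delta < tol:
            converged = True
            break

    if not converged:
        flags.append("did not converge")
        warnings.warn("Newton-Raphson did not converge within "
                      f"{max_iter} iterations", ConvergenceWarning, stacklevel=2)
    if np.any(np.abs(beta) > 15):
        flags.append("diverging coefficient (possible monotone likelihood / "
                     "complete separation)")
        warnings.warn("coefficient magnitude suggests complete separation",
                      ConvergenceWarning, stacklevel=2)

    info = -hess
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
        flags.append("singular information matrix")

    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    wald_p = 2.0 * stats.norm.sf(np.abs(z))
    wald_p = np.where(se > 0, wald_p, np.nan)
    return CoxFit(
        covariates=list(covariates),
        coef=beta,
        se=se,
        hazard_ratio=np.exp(beta),
        ci95_low=np.exp(beta - 1.96 * se),
        ci95_high=np.exp(beta + 1.96 * se),
        wald_p=wald_p,
        log_likelihood=float(ll),
        iterations=it,
        converged=converged,
        flags=flags,
    )


def _breslow_loglik_derivs(beta, X, time, event):
    """Breslow ties: Efron with the fractional correction switched off."""
    n, p = X.shape
    eta = X @ beta
    eta -= eta.max()
    w = np.exp(eta)
    order = np.argsort(time, kind="stable")[::-1]
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    S0, S1, S2 = 0.0, np.zeros(p), np.zeros((p, p))
    i = 0
    while i < n:
        t = time[order[i]]
        j = i
        block = []
        while j < n and time[order[j]] == t:
            idx = order[j]
            S0 += w[idx]
            S1 += w[idx] * X[idx]
            S2 += w[idx] * np.outer(X[idx], X[idx])
            if event[idx]:
                block.append(idx)
            j += 1
        d = len(block)
        if d:
            idxs = np.array(block)
            ll += eta[idxs].sum() - d * np.log(S0)
            grad += X[idxs].sum(axis=0) - d * S1 / S0
            hess -= d * (S2 / S0 - np.outer(S1, S1) / S0**2)
        i = j
    return ll, grad, hess


class CoxPH(BaseEstimator):
    """sklearn-style front end for :func:`cox_fit`.

    ``fit(X, y)`` accepts ``y`` as an ``(n, 2)`` array of (time, event) or a
    DataFrame with ``time``/``event`` columns; fitted attributes are
    ``coef_``, ``se_``, ``hazard_ratios_``, ``fit_`` (the full
    :class:`CoxFit`). ``predict(X)`` returns the linear predictor (log
    relative hazard).
    """

    def __init__(self, tie_method: str = "efron", max_iter: int = 50,
                 tol: float = 1e-9):
        self.tie_method = tie_method
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y) -> "CoxPH":
        if isinstance(y, pd.DataFrame):
            time, event = y["time"].to_numpy(), y["event"].to_numpy()
        else:
            y = np.asarray(y, dtype=float)
            time, event = y[:, 0], y[:, 1].astype(bool)
        self.fit_ = cox_fit(X, time, event, tie_method=self.tie_method,
                            max_iter=self.max_iter, tol=self.tol)
        self.coef_ = self.fit_.coef
        self.se_ = self.fit_.se
        self.hazard_ratios_ = self.fit_.hazard_ratio
        self.feature_names_in_ = np.asarray(self.fit_.covariates, dtype=object)
        return self

    def predict(self, X) -> np.ndarray:
        X = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return X @ self.coef_


# ---------------------------------------------------------------------------
# Survival-sample construction
# ---------------------------------------------------------------------------

def survival_from(cohort: pd.DataFrame, origin: str = "onset",
                  *, zero_floor: float = 0.5) -> pd.DataFrame:
    """Build (time, event) samples from a cohort table.

    ``origin="onset"`` uses follow-up from symptom onset directly;
    ``origin="admission"`` subtracts onset-to-admission delay. Zero
    durations (endpoint within the admission month) are floored at
    ``zero_floor`` months so those subjects enter the risk set -- the
    survival curve then starts below 1.
    """
    if origin not in ("onset", "admission"):
        raise ValueError(f"unknown origin {origin!r}")
    fu = cohort["followup_months_from_onset"].astype(float)
    if origin == "onset":
        time = fu.copy()
    else:
        time = fu - cohort["months_since_onset"].astype(float)
    if (time < 0).any():
        bad = cohort.index[time < 0].tolist()
        raise ValueError(f"negative survival durations for rows {bad}")
    time = time.where(time > 0, zero_floor)
    return pd.DataFrame({
        "time": time,
        "event": cohort["event"].astype(bool),
    }, index=cohort.index)
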