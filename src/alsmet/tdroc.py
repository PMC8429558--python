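"""Time-dependent ROC analysis for a baseline prognostic marker.

Cases at horizon t are subjects with the endpoint by t (cumulative cases),
controls are subjects event-free beyond t (dynamic controls). Censoring
before the horizon is handled by the classical Kaplan-Meier-weighted
estimator: with S the all-sample KM curve and S_c the KM curve within
{marker > c},

    sens(c) = (1 - S_c(t)) P(M > c) / (1 - S(t))
    1 - spec(c) = S_c(t) P(M > c) / S(t)

so the curve reduces exactly to the empirical ROC of the binary
"event by t" label when nobody is censored before the horizon. The raw
weighted estimates can be locally non-monotone under heavy censoring; the
curve is made non-decreasing (sweeping cutoffs downward) by a running
maximum and clipped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from sklearn.base import BaseEstimator

from .survival import km_estimate

__all__ = ["ROCCurve", "CutoffChoice", "td_roc", "auc", "select_cutoff",
           "TimeDependentROC"]


@dataclass(frozen=True)
class ROCCurve:
    cutoffs: np.ndarray            # descending, +inf first, -inf last
    sensitivity: np.ndarray        # P(M > c | case), non-decreasing
    one_minus_specificity: np.ndarray  # P(M > c | control), non-decreasing
    horizon: float
    auc: float


@dataclass(frozen=True)
class CutoffChoice:
    cutoff: float
    sensitivity: float
    specificity: float
    criterion: str


def _km_at(time, event, t: float) -> float:
    if len(time) == 0:
        return 1.0
    return km_estimate(time, event).survival_at(t)


def td_roc(marker, time, event, horizon: float,
           *, weighting: str = "km") -> ROCCurve:
    """Time-dependent ROC of a baseline marker at a fixed horizon.

    Parameters
    ----------
    marker : array
        Marker value per subject; must be complete (no NaN).
    time, event : arrays
        Right-censored survival data on the same subjects.
    horizon : float
        Evaluation time (months), > 0.
    weighting : {"km", "empirical"}
        "km" is the censoring-aware Kaplan-Meier-weighted estimator;
        "empirical" drops subjects censored before the horizon and computes
        the plain binary-outcome ROC.
    """
    marker = np.asarray(marker, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    if np.isnan(marker).any():
        raise ValueError("marker must be complete for all included subjects")
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if weighting not in ("km", "empirical"):
        raise ValueError(f"unknown weighting {weighting!r}")
    n = marker.size

    cutoffs = np.concatenate([[np.inf], np.unique(marker)[::-1], [-np.inf]])

    if weighting == "empirical":
        usable = (time > horizon) | (event & (time <= horizon))
        m, is_case = marker[usable], (event & (time <= horizon))[usable]
        n_case, n_ctrl = int(is_case.sum()), int((~is_case).sum())
        if n_case == 0 or n_ctrl == 0:
            raise ValueError("ROC undefined: no cases or no controls at horizon")
        sens = np.array([(m[is_case] > c).mean() for c in cutoffs])
        fpr = np.array([(m[~is_case] > c).mean() for c in cutoffs])
    else:
        S_all = _km_at(time, event, horizon)
        if not 0.0 < S_all < 1.0:
            raise ValueError("ROC undefined: no cases or no controls at horizon")
        sens = np.empty(cutoffs.size)
        fpr = np.empty(cutoffs.size)
        for i, c in enumerate(cutoffs):
            above = marker > c
            p_above = above.mean()
            if p_above == 0.0:
                s_c = 1.0
            else:
                s_c = _km_at(time[above], event[above], horizon)
            sens[i] = (1.0 - s_c) * p_above / (1.0 - S_all)
            fpr[i] = s_c * p_above / S_all
        sens = np.clip(sens, 0.0, 1.0)
        fpr = np.clip(fpr, 0.0, 1.0)
        # enforce monotone non-decreasing sweep from high cutoff to low
        sens = np.maximum.accumulate(sens)
        fpr = np.maximum.accumulate(fpr)

    # pin the infinite-cutoff endpoints
    sens[0], fpr[0] = 0.0, 0.0
    sens[-1], fpr[-1] = 1.0, 1.0
    curve = ROCCurve(cutoffs, sens, fpr, float(horizon), np.nan)
    return ROCCurve(cutoffs, sens, fpr, float(horizon), auc(curve))


def auc(curve: ROCCurve) -> float:
    """Area under the curve by trapezoidal integration over (FPR, TPR)."""
    x, y = np.asarray(curve.one_minus_specificity), np.asarray(curve.sensitivity)
    if x.size < 2:
        raise ValueError("need at least two curve points")
    order = np.lexsort((y, x))
    return float(np.trapezoid(y[order], x[order]))


def select_cutoff(curve: ROCCurve, criterion="youden") -> CutoffChoice:
    """Pick an operating point on a time-dependent ROC curve.

    ``criterion="youden"`` maximises sensitivity + specificity - 1, ties
    broken toward the smaller cutoff; a numeric criterion is a preset
    threshold whose curve coordinates are reported verbatim (the finite
    curve cutoff closest from below, since classification is marker > c).
    """
    cutoffs = np.asarray(curve.cutoffs, dtype=float)
    sens = np.asarray(curve.sensitivity, dtype=float)
    spec = 1.0 - np.asarray(curve.one_minus_specificity, dtype=float)
    if cutoffs.size == 0:
        raise ValueError("empty curve")
    if criterion == "youden":
        finite = np.isfinite(cutoffs)
        j = sens[finite] + spec[finite] - 1.0
        c_f, s_f, sp_f = cutoffs[finite], sens[finite], spec[finite]
        best = np.nonzero(j == j.max())[0]
        pick = best[np.argmin(c_f[best])]
        return CutoffChoice(float(c_f[pick]), float(s_f[pick]),
                            float(sp_f[pick]), "youden")
    c = float(criterion)
    finite = np.isfinite(cutoffs)
    candidates = np.nonzero(finite & (cutoffs <= c))[0]
    idx = candidates[np.argmax(cutoffs[candidates])] if candidates.size else cutoffs.size - 1
    return CutoffChoice(c, float(sens[idx]), float(spec[idx]), "preset")


class TimeDependentROC(BaseEstimator):
    """Estimator wrapper: ``fit(marker, time, event)`` stores ``curve_``,
    ``auc_``; ``select(criterion)`` returns a :class:`CutoffChoice`."""

    def __init__(self, horizon: float = 24.0, weighting: str = "km"):
        self.horizon = horizon
        self.weighting = weighting

    def fit(self, marker, time, event) -> "TimeDependentROC":
        self.curve_ = td_roc(marker, time, event, self.horizon,
                             weighting=self.weighting)
        self.auc_ = self.curve_.auc
        return self

    def select(self, criterion="youden") -> CutoffChoice:
        return select_cutoff(self.curve_, criterion)
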