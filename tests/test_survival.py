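"""Kaplan-Meier, log-rank and Cox against hand computations and independent
oracles (lifelines, brute-force partial-likelihood maximisation)."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from alsmet import km_estimate, logrank_test, cox_fit, survival_from, CoxPH
from alsmet.survival import ConvergenceWarning


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

def test_km_all_censored():
    curve = km_estimate([3.0, 5.0, 8.0], [False, False, False])
    assert curve.event_times.size == 0
    assert np.isnan(curve.median_survival)


def test_km_no_censoring_is_empirical():
    curve = km_estimate([1.0, 2.0, 3.0], [True, True, True])
    assert np.allclose(curve.survival, [2 / 3, 1 / 3, 0.0])
    assert curve.median_survival == 2.0


def test_km_hand_product_limit():
    # times 1+, 2, 3+, 4 (+ = censored): S(2) = 3/4? no -- risk set at 2 is 3
    curve = km_estimate([1.0, 2.0, 3.0, 4.0], [False, True, False, True])
    assert curve.survival_at(2.0) == pytest.approx(2 / 3)
    assert curve.survival_at(4.0) == pytest.approx(0.0)


def test_km_ties_events_before_censorings():
    # censored at t stays in the risk set for the event at t
    curve = km_estimate([5.0, 5.0], [True, False])
    assert curve.at_risk[0] == 2
    assert curve.survival[0] == pytest.approx(0.5)


@pytest.mark.parametrize("seed", range(5))
def test_km_empirical_property_random(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 50))
    t = rng.exponential(10.0, n).round(3) + 0.001
    curve = km_estimate(t, np.ones(n, bool))
    for tt in rng.uniform(0, 30, 10):
        assert curve.survival_at(tt) == pytest.approx((t > tt).mean())


def test_km_matches_lifelines():
    from lifelines import KaplanMeierFitter
    rng = np.random.default_rng(42)
    t = rng.exponential(12.0, 80)
    e = rng.random(80) < 0.7
    curve = km_estimate(t, e)
    kmf = KaplanMeierFitter().fit(t, e)
    for tt in curve.event_times:
        assert curve.survival_at(tt) == pytest.approx(
            float(kmf.predict(tt)), abs=1e-10)


# ---------------------------------------------------------------------------
# Log-rank
# ---------------------------------------------------------------------------

def test_logrank_identical_groups():
    t = [1.0, 2.0, 5.0, 7.0]
    e = [True, True, False, True]
    res = logrank_test([t, t], [e, e])
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p == pytest.approx(1.0)


def test_logrank_hand_oracle_two_groups():
    """Brute-force O-E and hypergeometric variance over the 4 event times."""
    tA, eA = np.array([1.0, 2.0]), np.array([True, True])
    tB, eB = np.array([3.0, 4.0]), np.array([True, True])
    t = np.concatenate([tA, tB])
    g = np.array([0, 0, 1, 1])
    omE, V = 0.0, 0.0
    for tt in sorted(t):
        at = t >= tt
        N, d = at.sum(), 1
        nA = (at & (g == 0)).sum()
        dA = 1 if (tt in tA) else 0
        omE += dA - d * nA / N
        V += d * (N - d) / (N - 1) * (nA / N) * (1 - nA / N) if N > 1 else 0.0
    expected_stat = omE**2 / V
    res = logrank_test([tA, tB], [eA, eB])
    assert res.statistic == pytest.approx(expected_stat, rel=1e-10)
    assert res.df == 1


def test_logrank_maximal_separation():
    res = logrank_test([[10.0, 12.0], [1.0, 2.0]],
                       [[False, False], [True, True]])
    assert res.statistic > 0


def test_logrank_requires_events():
    with pytest.raises(ValueError):
        logrank_test([[1.0], [2.0]], [[False], [False]])


def test_logrank_invariances():
    rng = np.random.default_rng(3)
    tA, tB = rng.exponential(10, 30), rng.exponential(16, 25)
    eA, eB = rng.random(30) < 0.8, rng.random(25) < 0.8
    base = logrank_test([tA, tB], [eA, eB])
    relabel = logrank_test([tB, tA], [eB, eA])
    assert relabel.statistic == pytest.approx(base.statistic, rel=1e-9)
    # strictly monotone time transform preserves risk-set structure
    mono = logrank_test([np.sqrt(tA), np.sqrt(tB)], [eA, eB])
    assert mono.statistic == pytest.approx(base.statistic, rel=1e-9)


def test_logrank_matches_lifelines_multigroup():
    from lifelines.statistics import multivariate_logrank_test
    rng = np.random.default_rng(11)
    times = [rng.exponential(s, 40) for s in (8.0, 12.0, 20.0)]
    events = [rng.random(40) < 0.75 for _ in range(3)]
    res = logrank_test(times, events)
    df = pd.DataFrame({
        "t": np.concatenate(times),
        "e": np.concatenate(events),
        "g": np.repeat([0, 1, 2], 40),
    })
    ll = multivariate_logrank_test(df.t, df.g, df.e)
    assert res.statistic == pytest.approx(ll.test_statistic, rel=1e-8)
    assert res.p == pytest.approx(ll.p_value, rel=1e-8)


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

def _partial_loglik_binary(beta, x, t, e):
    """Independent partial likelihood for tie-free data (exact form)."""
    ll = 0.0
    for i in np.nonzero(e)[0]:
        risk = t >= t[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


def test_cox_constant_covariate_flagged_zero():
    rng = np.random.default_rng(0)
    t = rng.exponential(10, 30)
    e = np.ones(30, bool)
    with pytest.warns(ConvergenceWarning):
        fit = cox_fit(np.ones((30, 1)), t, e)
    assert fit.coef[0] == pytest.approx(0.0, abs=1e-8)
    assert any("constant" in f or "rank" in f for f in fit.flags)


@pytest.mark.parametrize("seed", range(10))
def test_cox_grid_search_oracle(seed):
    """Newton-Raphson equals direct 1-D maximisation of the partial
    likelihood on tie-free single-binary-covariate data."""
    rng = np.random.default_rng(seed)
    n = 20
    x = (rng.random(n) < 0.5).astype(float)
    t = rng.exponential(np.exp(-0.8 * x) * 10)
    e = rng.random(n) < 0.8
    if e.sum() == 0 or len(np.unique(x[e])) < 2:
        e[:2] = True
    fit = cox_fit(x, t, e)
    opt = minimize_scalar(lambda b: -_partial_loglik_binary(b, x, t, e),
                          bounds=(-6, 6), method="bounded",
                          options={"xatol": 1e-10})
    assert fit.coef[0] == pytest.approx(opt.x, abs=1e-4)


def test_cox_matches_lifelines_efron():
    from lifelines import CoxPHFitter
    rng = np.random.default_rng(5)
    n = 120
    X = pd.DataFrame({"a": rng.normal(size=n),
                      "b": (rng.random(n) < 0.4).astype(float)})
    t = np.ceil(rng.exponential(np.exp(-(0.5 * X.a - 0.7 * X.b)) * 10))  # ties
    e = rng.random(n) < 0.8
    fit = cox_fit(X, t, e)
    df = X.assign(t=t, e=e.astype(int))
    llf = CoxPHFitter().fit(df, "t", "e")
    # lifelines stops at a looser step tolerance than our 1e-9
    assert fit.coef == pytest.approx(llf.params_.to_numpy(), abs=1e-4)
    assert fit.se == pytest.approx(llf.standard_errors_.to_numpy(), abs=1e-4)
    assert fit.hazard_ratio == pytest.approx(np.exp(llf.params_).to_numpy(), rel=1e-4)


def test_cox_breslow_maximises_breslow_likelihood():
    rng = np.random.default_rng(8)
    n = 100
    X = pd.DataFrame({"a": rng.normal(size=n)})
    t = np.ceil(rng.exponential(np.exp(-0.6 * X.a) * 8))
    e = rng.random(n) < 0.75
    fit = cox_fit(X, t, e, tie_method="breslow")
    from alsmet.survival import _breslow_loglik_derivs
    Xc = X.to_numpy() - X.to_numpy().mean(axis=0)
    t_arr = np.asarray(t, dtype=float)
    ll_at_fit = _breslow_loglik_derivs(fit.coef, Xc, t_arr, e)[0]
    for delta in (-1e-3, 1e-3):
        ll_near = _breslow_loglik_derivs(fit.coef + delta, Xc, t_arr, e)[0]
        assert ll_near <= ll_at_fit + 1e-12


def test_cox_rank_deficiency_detected():
    rng = np.random.default_rng(2)
    x = rng.normal(size=40)
    X = np.column_stack([x, x])  # duplicated column
    t = rng.exponential(10, 40)
    e = np.ones(40, bool)
    with pytest.warns(ConvergenceWarning):
        fit = cox_fit(X, t, e)
    assert any("rank" in f for f in fit.flags)


def test_cox_separation_flagged():
    # marker perfectly orders events before censorings: monotone likelihood
    t = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
    e = np.array([True, True, True, False, False, False])
    x = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
    with pytest.warns(ConvergenceWarning):
        fit = cox_fit(x, t, e)
    assert any("separation" in f or "diverging" in f for f in fit.flags)


def test_cox_affine_rescaling():
    rng = np.random.default_rng(9)
    n = 80
    x = rng.normal(size=n)
    t = rng.exponential(np.exp(-0.5 * x) * 10)
    e = rng.random(n) < 0.8
    f1 = cox_fit(x, t, e)
    a = 4.0
    f2 = cox_fit(a * x + 3.0, t, e)
    assert f2.coef[0] == pytest.approx(f1.coef[0] / a, rel=1e-6)
    assert f2.se[0] == pytest.approx(f1.se[0] / a, rel=1e-6)


def test_coxph_estimator_api():
    rng = np.random.default_rng(1)
    n = 60
    X = pd.DataFrame({"z": rng.normal(size=n)})
    t = rng.exponential(np.exp(-0.5 * X.z) * 10)
    e = rng.random(n) < 0.8
    model = CoxPH().fit(X, np.column_stack([t, e]))
    assert model.coef_.shape == (1,)
    assert model.get_params()["tie_method"] == "efron"
    lp = model.predict(X)
    assert lp == pytest.approx(X.to_numpy() @ model.coef_)


# ---------------------------------------------------------------------------
# survival_from
# ---------------------------------------------------------------------------

def test_survival_from_origins():
    df = pd.DataFrame({
        "months_since_onset": [10.0, 10.0, 5.0],
        "followup_months_from_onset": [30.0, 10.0, 25.0],
        "event": [1, 1, 0],
    })
    onset = survival_from(df, "onset")
    assert list(onset["time"]) == [30.0, 10.0, 25.0]
    adm = survival_from(df, "admission")
    assert adm["time"].iloc[0] == 20.0
    assert adm["time"].iloc[1] == 0.5  # endpoint within the admission month
    with pytest.raises(ValueError):
        survival_from(df, "diagnosis")
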