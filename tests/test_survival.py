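"""Survival layer: hand examples, brute-force oracles, lifelines cross-checks,
simulation-based coverage properties."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test

from brcascreen.survival import (ConvergenceError, CoxPH, KaplanMeier,
                                 cox_fit, km_fit, km_risk_at, logrank)


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

def test_km_hand_example():
    # classic 3-subject worked example:
    # event at 5 (3 at risk), censored at 10, event at 15 (1 at risk)
    res = km_fit([5.0, 10.0, 15.0], [True, False, True])
    assert res.survival_at(4.9) == 1.0
    assert res.survival_at(5.0) == pytest.approx(2.0 / 3.0)
    assert res.survival_at(12.0) == pytest.approx(2.0 / 3.0)
    assert res.survival_at(15.0) == 0.0
    assert km_risk_at(res, 12.0) == pytest.approx(1.0 / 3.0)


def test_km_matches_brute_force_product():
    rng = np.random.default_rng(4)
    t = np.round(rng.exponential(10, size=200), 0) + 1
    e = rng.random(200) < 0.6
    res = km_fit(t, e)
    for i, u in enumerate(res.times):
        prod = 1.0
        for v in res.times[: i + 1]:
            d = ((t == v) & e).sum()
            r = (t >= v).sum()
            prod *= 1 - d / r
        assert res.survival[i] == pytest.approx(prod, rel=1e-12)


def test_km_matches_lifelines():
    rng = np.random.default_rng(9)
    t = np.round(rng.gamma(4, 12, size=500), 0) + 1
    e = rng.random(500) < 0.4
    ours = km_fit(t, e)
    kmf = KaplanMeierFitter().fit(t, e)
    for age in [5.0, 20.0, 45.0, 70.0, 120.0]:
        assert ours.survival_at(age) == pytest.approx(
            float(kmf.predict(age)), abs=1e-12)


def test_km_no_events_warns_and_stays_one():
    with pytest.warns(UserWarning, match="no events"):
        res = km_fit([3.0, 4.0], [False, False])
    assert res.survival_at(100.0) == 1.0
    assert res.times.size == 0


def test_km_no_censoring_is_ecdf():
    t = np.array([2.0, 3.0, 3.0, 7.0, 9.0])
    res = km_fit(t, np.ones(5, dtype=bool))
    for age in [1.0, 2.0, 3.0, 8.0, 9.0]:
        assert res.survival_at(age) == pytest.approx((t > age).mean())


def test_km_input_validation():
    with pytest.raises(ValueError):
        km_fit([], [])
    with pytest.raises(ValueError):
        km_fit([1.0, -2.0], [True, True])
    with pytest.raises(ValueError):
        km_fit([1.0, 2.0], [True])
    with pytest.raises(ValueError):
        KaplanMeier([1.0], [True]).fit().survival_at(-5.0)


def test_km_ci_contains_estimate_and_is_ordered():
    rng = np.random.default_rng(2)
    t = rng.integers(1, 50, 300).astype(float)
    e = rng.random(300) < 0.5
    res = km_fit(t, e)
    assert np.all(res.ci_lower <= res.survival + 1e-12)
    assert np.all(res.survival <= res.ci_upper + 1e-12)


# ---------------------------------------------------------------------------
# Cox model
# ---------------------------------------------------------------------------

def _sim_two_group(n=600, hr=2.0, seed=0, round_ages=True):
    rng = np.random.default_rng(seed)
    x = (rng.random(n) < 0.5).astype(float)
    t = rng.exponential(1.0 / (0.05 * hr**x))
    c = rng.exponential(30.0, size=n)
    obs = np.minimum(t, c)
    if round_ages:
        obs = np.floor(obs) + 1.0
    return pd.DataFrame({"time": obs, "event": t <= c, "x": x})


def test_cox_matches_lifelines_with_heavy_ties():
    df = _sim_two_group(n=800, hr=2.5, seed=3)
    ours = cox_fit(df)
    cph = CoxPHFitter().fit(df, duration_col="time", event_col="event")
    # agreement is limited only by the two optimizers' stopping rules
    assert ours.params["x"] == pytest.approx(cph.params_["x"], abs=1e-5)
    assert ours.bse["x"] == pytest.approx(cph.standard_errors_["x"], abs=1e-5)
    assert ours.loglik == pytest.approx(cph.log_likelihood_, abs=1e-6)


def test_cox_multivariate_matches_lifelines():
    rng = np.random.default_rng(12)
    n = 700
    x1 = rng.normal(size=n)
    x2 = (rng.random(n) < 0.3).astype(float)
    t = rng.exponential(1.0 / (0.03 * np.exp(0.5 * x1 + 0.8 * x2)))
    c = rng.exponential(40.0, size=n)
    df = pd.DataFrame({"time": np.floor(np.minimum(t, c)) + 1,
                       "event": t <= c, "x1": x1, "x2": x2})
    ours = cox_fit(df)
    cph = CoxPHFitter().fit(df, duration_col="time", event_col="event")
    for name in ("x1", "x2"):
        assert ours.params[name] == pytest.approx(cph.params_[name], abs=1e-5)
        assert ours.bse[name] == pytest.approx(
            cph.standard_errors_[name], abs=1e-5)


def test_cox_fitted_loglik_beats_null():
    df = _sim_two_group(seed=8)
    res = cox_fit(df)
    assert res.loglik >= res.loglik_null


def test_cox_identical_groups_gives_null_hr():
    rng = np.random.default_rng(1)
    n = 500
    t = np.floor(rng.exponential(20, n)) + 1
    e = rng.random(n) < 0.5
    x = (np.arange(n) % 2).astype(float)  # label carries no signal
    res = CoxPH(t, e, pd.DataFrame({"x": x})).fit()
    ci = res.conf_int()
    assert ci.loc["x", "hr_lower"] < 1.0 < ci.loc["x", "hr_upper"]


def test_cox_ci_coverage_under_true_model():
    """95% Wald interval covers the true log-HR in >= 89/100 replicates."""
    covered = 0
    for seed in range(100):
        df = _sim_two_group(n=300, hr=2.0, seed=seed, round_ages=False)
        ci = cox_fit(df).conf_int()
        if ci.loc["x", "hr_lower"] <= 2.0 <= ci.loc["x", "hr_upper"]:
            covered += 1
    assert covered >= 89, covered


def test_cox_input_validation():
    t = np.array([1.0, 2.0, 3.0, 4.0])
    e = np.array([True, True, False, False])
    with pytest.raises(ValueError, match="constant"):
        CoxPH(t, e, pd.DataFrame({"x": [1.0, 1.0, 1.0, 1.0]}))
    with pytest.raises(ValueError, match="2 events"):
        CoxPH(t, np.array([True, False, False, False]),
              pd.DataFrame({"x": [0.0, 1.0, 0.0, 1.0]}))
    with pytest.raises(ValueError, match="finite"):
        CoxPH(t, e, pd.DataFrame({"x": [0.0, np.nan, 1.0, 0.0]}))


def test_cox_separation_raises_or_flags():
    # perfectly separated: all events in one arm before any other subject
    t = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
    e = np.array([True, True, True, False, False, False])
    x = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
    try:
        res = CoxPH(t, e, pd.DataFrame({"x": x})).fit()
    except ConvergenceError:
        return
    assert res.separation_flag


def test_cox_summary_shape():
    res = cox_fit(_sim_two_group(seed=5))
    table = res.summary()
    assert list(table.columns) == ["coef", "se", "hr", "hr_lower", "hr_upper", "p"]
    assert table.index.tolist() == ["x"]
    assert res.hazard_ratios["x"] == pytest.approx(np.exp(res.params["x"]))


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------

def test_logrank_identical_arms_is_zero():
    t = np.array([3.0, 5.0, 8.0, 10.0])
    e = np.array([True, False, True, True])
    chi2, p = logrank(t, e, t, e)
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_logrank_symmetry():
    a = (np.array([2.0, 4.0, 6.0, 9.0]), np.array([True, True, False, True]))
    b = (np.array([3.0, 5.0, 7.0, 8.0]), np.array([True, False, True, True]))
    chi_ab, p_ab = logrank(*a, *b)
    chi_ba, p_ba = logrank(*b, *a)
    assert chi_ab == pytest.approx(chi_ba, rel=1e-12)
    assert p_ab == pytest.approx(p_ba, rel=1e-12)


def test_logrank_hand_computation():
    # arm A: events at 1, 2; arm B: events at 3, censored at 4
    ta, ea = np.array([1.0, 2.0, 5.0]), np.array([True, True, False])
    tb, eb = np.array([3.0, 4.0, 6.0]), np.array([True, False, False])
    # time 1: 6 at risk (3 A), 1 death in A -> E_A += 1*3/6
    # time 2: 5 at risk (2 A), 1 death in A -> E_A += 1*2/5
    # time 3: 4 at risk (1 A), 1 death in B -> E_A += 1*1/4
    obs_a = 2.0
    exp_a = 3 / 6 + 2 / 5 + 1 / 4
    var = (
        1 * (3 / 6) * (1 - 3 / 6) * (6 - 1) / (6 - 1)
        + 1 * (2 / 5) * (1 - 2 / 5) * (5 - 1) / (5 - 1)
        + 1 * (1 / 4) * (1 - 1 / 4) * (4 - 1) / (4 - 1)
    )
    expected_chi2 = (obs_a - exp_a) ** 2 / var
    chi2, _ = logrank(ta, ea, tb, eb)
    assert chi2 == pytest.approx(expected_chi2, rel=1e-12)


def test_logrank_matches_lifelines():
    rng = np.random.default_rng(6)
    ta = np.floor(rng.exponential(10, 150)) + 1
    ea = rng.random(150) < 0.7
    tb = np.floor(rng.exponential(14, 130)) + 1
    eb = rng.random(130) < 0.7
    chi2, p = logrank(ta, ea, tb, eb)
    ref = logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
    assert chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
    assert p == pytest.approx(ref.p_value, rel=1e-9)


def test_logrank_requires_events():
    with pytest.raises(ValueError):
        logrank([1.0, 2.0], [False, False], [3.0], [False])
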