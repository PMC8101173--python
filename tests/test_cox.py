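import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar

import hazstrat as hs
from conftest import make_sample

BHAT = -0.5 * np.log(2.0)


# ---------------------------------------------------------------------------
# partial likelihood and estimation
# ---------------------------------------------------------------------------


class TestWorkedExample:
    def test_beta_hat_analytic(self, three_subject):
        fit = hs.fit_cox(three_subject, ["x"])
        assert fit.coefficients["x"] == pytest.approx(BHAT, abs=1e-7)

    def test_loglik_values(self, three_subject):
        assert hs.partial_loglik(three_subject, ["x"], [0.0]) == pytest.approx(-np.log(6))
        assert hs.partial_loglik(three_subject, ["x"], [BHAT]) == pytest.approx(-1.76275, abs=1e-5)

    def test_null_model_loglik_is_log_risk_sets(self, three_subject):
        fit = hs.fit_cox_null(three_subject)
        assert fit.loglik == pytest.approx(-(np.log(3) + np.log(2)))

    def test_aic(self, three_subject):
        fit = hs.fit_cox(three_subject, ["x"])
        assert hs.aic(fit) == pytest.approx(5.5255, abs=1e-3)

    def test_schoenfeld_residuals_at_bhat(self, three_subject):
        fit = hs.fit_cox(three_subject, ["x"])
        r = hs.schoenfeld_residuals(fit).schoenfeld["x"].to_numpy()
        assert r == pytest.approx([0.41421, -0.41421], abs=1e-4)
        assert r.sum() == pytest.approx(0.0, abs=1e-7)

    def test_schoenfeld_residuals_at_zero(self, three_subject):
        fit = hs.fit_cox(three_subject, ["x"], initial_beta=[0.0], max_iter=0)
        r = hs.schoenfeld_residuals(fit).schoenfeld["x"].to_numpy()
        assert r[0] == pytest.approx(1 / 3)


def test_symmetric_groups_give_zero_beta():
    s = make_sample([1, 2, 3, 1, 2, 3], [1, 1, 0, 1, 1, 0], x=[0, 0, 0, 1, 1, 1])
    fit = hs.fit_cox(s, ["x"])
    assert fit.coefficients["x"] == pytest.approx(0.0, abs=1e-9)


def test_constant_covariate_is_degenerate(three_subject):
    s = make_sample([1.0, 2.0, 3.0], [1, 1, 0], c=[2.0, 2.0, 2.0])
    with pytest.raises(hs.DegenerateDesignError):
        hs.fit_cox(s, ["c"])


def test_monotone_likelihood_raises():
    # perfect separation: the covariate orders the event times exactly
    s = make_sample([1, 2, 3, 4], [1, 1, 1, 1], x=[3.0, 2.0, 1.0, 0.0])
    with pytest.raises(hs.ConvergenceError):
        hs.fit_cox(s, ["x"])


@st.composite
def cox_samples(draw):
    n = draw(st.integers(2, 6))
    times = draw(st.lists(st.floats(0.2, 9.0), min_size=n, max_size=n, unique=True))
    events = draw(st.lists(st.integers(0, 1), min_size=n, max_size=n))
    x = draw(st.lists(st.sampled_from([0.0, 0.5, 1.0, 2.0]), min_size=n, max_size=n))
    return times, events, x


@given(cox_samples())
def test_fit_matches_grid_search_oracle(data):
    """Newton-Raphson equals a 1-d maximizer of the partial likelihood."""
    times, events, x = data
    s = make_sample(times, events, x=x)
    if s.events.sum() == 0 or np.ptp(x) == 0:
        return
    try:
        fit = hs.fit_cox(s, ["x"])
    except (hs.ConvergenceError, hs.DegenerateDesignError):
        return
    res = minimize_scalar(
        lambda b: -hs.partial_loglik(s, ["x"], [b]), bounds=(-3, 3), method="bounded",
        options={"xatol": 1e-10},
    )
    if abs(res.x) > 2.5:  # oracle pinned at the box: near-monotone likelihood
        return
    assert fit.coefficients["x"] == pytest.approx(res.x, abs=1e-4)


def test_shift_invariance_of_hazard_ratios(ph_sample):
    """Adding a constant to a covariate changes no HR and no AIC."""
    fit0 = hs.fit_cox(ph_sample, ["z"])
    shifted = ph_sample.df.copy()
    shifted["z"] = shifted["z"] + 17.3
    fit1 = hs.fit_cox(hs.SurvivalSample(shifted), ["z"])
    assert fit1.coefficients["z"] == pytest.approx(fit0.coefficients["z"], abs=1e-6)
    assert hs.aic(fit1) == pytest.approx(hs.aic(fit0), abs=1e-5)


def test_lifelines_cross_check(ph_sample):
    from lifelines import CoxPHFitter

    fit = hs.fit_cox(ph_sample, ["z"])
    cph = CoxPHFitter().fit(ph_sample.df[["time", "event", "z"]], "time", "event")
    assert fit.coefficients["z"] == pytest.approx(cph.params_["z"], abs=1e-5)
    assert fit.standard_errors()["z"] == pytest.approx(cph.standard_errors_["z"], abs=1e-5)
    assert fit.loglik == pytest.approx(cph.log_likelihood_, abs=1e-4)


def test_efron_ties_match_lifelines():
    from lifelines import CoxPHFitter

    s = make_sample([1, 1, 1, 2, 2, 3, 4, 4], [1, 1, 0, 1, 1, 0, 1, 0],
                    x=[1.0, 0.0, 1.0, 0.0, 1.0, 0.0, 1.0, 0.0])
    fit = hs.fit_cox(s, ["x"])
    cph = CoxPHFitter().fit(s.df[["time", "event", "x"]], "time", "event")
    assert fit.coefficients["x"] == pytest.approx(cph.params_["x"], abs=1e-6)


# ---------------------------------------------------------------------------
# baseline and residuals
# ---------------------------------------------------------------------------


def test_breslow_baseline_identity(ph_sample):
    """Summed estimated intensities equal the event total exactly."""
    fit = hs.fit_cox(ph_sample, ["z"])
    m = hs.martingale_residuals(fit).martingale
    assert m.sum() == pytest.approx(0.0, abs=1e-8)
    assert (m <= 1.0 + 1e-12).all()


def test_null_martingale_residual_of_early_censored_subject():
    s = make_sample([1.0, 1.0, 2.0, 3.0], [1, 0, 1, 0])
    fit = hs.fit_cox_null(s)
    m = hs.martingale_residuals(fit).martingale
    # subject censored at the first event time: -1/n increment
    assert m.loc[1] == pytest.approx(-1 / 4)


def test_null_baseline_equals_nelson_aalen(ph_sample):
    fit = hs.fit_cox_null(ph_sample)
    na = hs.nelson_aalen(ph_sample)
    tq = np.quantile(ph_sample.times, [0.2, 0.5, 0.8])
    assert fit.baseline(tq) == pytest.approx(na(tq), abs=1e-12)


def test_martingale_smooth_reveals_exponential_form():
    scn = hs.SimScenario(
        n=2000, family="multiplicative", baseline=0.25,
        covariates={"z": ("normal", 0.0, 1.0)},
        effects={"z": hs.EffectSpec(0.4, hs.FunctionalForm("scaled_exponential", c=1.0))},
        censoring_time=1.0,
    )
    s = hs.simulate_multiplicative(scn, seed=21)
    nullfit = hs.fit_cox_null(s)
    res = hs.martingale_residuals(nullfit)
    x = s.covariate("z")
    xs, sm = res.smooth_martingale(x)
    # increasing in z, with the steepening the exponential effect implies
    assert sm[-1] > sm[0]

    def rel_dev(xv, yv):
        # secant deviation on the central 90% (lowess tails are unstable)
        a, b = int(0.05 * len(xv)), int(0.95 * len(xv))
        xv, yv = xv[a:b], yv[a:b]
        sec = yv[0] + (yv[-1] - yv[0]) * (xv - xv[0]) / (xv[-1] - xv[0])
        return np.max(np.abs(yv - sec)) / np.ptp(yv)

    # curved against z, near-straight against exp(z)
    xs2, sm2 = res.smooth_martingale(np.exp(x))
    assert rel_dev(xs, sm) > 0.15
    assert rel_dev(xs2, sm2) < 0.1


# ---------------------------------------------------------------------------
# PH test
# ---------------------------------------------------------------------------


def test_ph_test_requires_three_events():
    s = make_sample([1.0, 2.0, 3.0], [1, 1, 0], x=[1.0, 0.0, 1.0])
    fit = hs.fit_cox(s, ["x"])
    with pytest.raises(hs.SurvivalDataError):
        hs.ph_test(fit)


def test_ph_test_degenerate_residuals_satisfied():
    # covariate identical across every subject -> residuals all zero
    s = make_sample([1, 2, 3, 4], [1, 1, 1, 0], x=[1.0, 1.0, 1.0, 1.0])
    fit = hs.fit_cox(s, ["x"], initial_beta=[0.0], max_iter=0)
    tab = hs.ph_test(fit)
    assert tab.loc["x", "p"] == 1.0 and bool(tab.loc["x", "satisfied"])


def test_ph_test_detects_decaying_effect():
    scn = hs.SimScenario(
        n=500, family="multiplicative", baseline=0.8,
        covariates={"z": ("bernoulli", 0.5)},
        effects={"z": hs.EffectSpec(((0.0, 1.0), (2.0, -1.0)))},
        censoring_time=2.0,
    )
    s = hs.simulate_multiplicative(scn, seed=31)
    fit = hs.fit_cox(s, ["z"])
    assert not hs.ph_test(fit)["satisfied"].all()


# ---------------------------------------------------------------------------
# time-varying coefficients, scans
# ---------------------------------------------------------------------------


def test_time_varying_fit_equals_episode_split_fit(ph_sample):
    """Direct basis evaluation equals an explicit episode-split Cox fit."""
    sub = ph_sample.subset(np.arange(120))
    fit = hs.fit_cox(sub, ["z"], time_varying={"z": hs.TimeVaryingSpec("linear")})
    ev = np.unique(sub.times[sub.events == 1])
    cp = hs.split_episodes(sub, list(ev))
    df = cp.df.copy()
    df["z_t"] = df["z"] * df["stop"]
    cp2 = hs.CountingProcessSample(df)
    fit2 = hs.fit_cox(cp2, ["z", "z_t"])
    assert fit.coefficients.to_numpy() == pytest.approx(fit2.coefficients.to_numpy(), abs=1e-6)


def test_time_varying_linear_recovers_slope():
    scn = hs.SimScenario(
        n=2000, family="multiplicative", baseline=0.4,
        covariates={"z": ("bernoulli", 0.5)},
        effects={"z": hs.EffectSpec(((0.0, 0.8), (3.0, -0.4)))},  # 0.8 - 0.4 t
        censoring_time=3.0,
    )
    s = hs.simulate_multiplicative(scn, seed=17)
    fit = hs.fit_cox(s, ["z"], time_varying={"z": hs.TimeVaryingSpec("linear")})
    se = fit.standard_errors()
    assert abs(fit.coefficients["z"] - 0.8) < 3 * se["z"]
    assert abs(fit.coefficients["z:t"] - (-0.4)) < 3 * se["z:t"]


def test_functional_form_candidates_and_skip(ph_sample):
    sub = ph_sample.subset(np.arange(200))
    cands = [
        hs.FunctionalForm("identity"),
        hs.FunctionalForm("polynomial", powers=(1, 2)),
        hs.FunctionalForm("fractional_polynomial", powers=(0.5,)),  # needs x>0: skipped
    ]
    scan = hs.functional_form_scan(sub, "z", cands)
    assert len(scan) == 3
    assert scan["skipped"].str.len().gt(0).sum() == 1  # the fp candidate
    assert scan["aic"].iloc[0] <= scan["aic"].dropna().iloc[-1]


def test_breakpoint_scan_single_point(ph_sample):
    sub = ph_sample.subset(np.arange(300))
    tmid = float(np.median(sub.times[sub.events == 1]))
    best, profile = hs.breakpoint_scan(sub, "z", [tmid])
    assert best == tmid and len(profile) == 1


def test_breakpoint_scan_recovers_true_break():
    scn = hs.SimScenario(
        n=2000, family="multiplicative", baseline=0.6,
        covariates={"z": ("bernoulli", 0.5)},
        effects={"z": hs.EffectSpec(((0.0, 1.5), (0.5, 0.0), (3.0, 0.0)))},
        censoring_time=3.0,
    )
    s = hs.simulate_multiplicative(scn, seed=19)
    best, _ = hs.breakpoint_scan(s, "z", np.linspace(0.1, 1.5, 15))
    assert abs(best - 0.5) <= 0.31


# ---------------------------------------------------------------------------
# functional forms
# ---------------------------------------------------------------------------


def test_functional_form_columns():
    x = np.array([50.0, 75.0])
    f = hs.FunctionalForm("scaled_exponential", c=100.0)
    assert f.columns(x, "age").iloc[:, 0].to_numpy() == pytest.approx(np.exp(x / 100))
    pw = hs.FunctionalForm(
        "piecewise_threshold", cutoff=70.0,
        base=hs.FunctionalForm("scaled_exponential", c=10.0),
    )
    cols = pw.columns(x, "age")
    assert cols.shape[1] == 2
    assert cols.iloc[0, 1] == 0.0  # below cutoff: supplementary term inactive
    assert cols.iloc[1, 1] == pytest.approx(np.exp((75.0 - 70.0) / 10.0))
    ident = hs.FunctionalForm("identity")
    assert ident.columns(x, "age")["age"].to_numpy() == pytest.approx(x)
    back = hs.FunctionalForm.from_dict(pw.to_dict())
    assert back == pw


def test_time_varying_spec_coefficient_counts():
    assert hs.TimeVaryingSpec("constant").n_coefficients == 1
    assert hs.TimeVaryingSpec("linear").n_coefficients == 2
    assert hs.TimeVaryingSpec("linear_with_break", break_time=0.2).n_coefficients == 3
    with pytest.raises(ValueError):
        hs.TimeVaryingSpec("linear_with_break").basis_functions("x")
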