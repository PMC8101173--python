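import json
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import hazstrat as hs
from conftest import make_sample


# ---------------------------------------------------------------------------
# Aalen estimator
# ---------------------------------------------------------------------------


def test_intercept_only_equals_nelson_aalen(ph_sample):
    fit = hs.fit_aalen(ph_sample, [])
    na = hs.nelson_aalen(ph_sample)
    assert fit.cumulative["intercept"].to_numpy() == pytest.approx(na(fit.times), abs=1e-10)
    assert fit.cumulative.iloc[0].to_numpy()[0] == pytest.approx(1 / ph_sample.n)


def test_two_group_closed_form(two_group):
    fit = hs.fit_aalen(two_group, ["g"])
    assert fit.cumulative["g"].iloc[-1] == pytest.approx(1.0)
    assert fit.cumulative["intercept"].iloc[-1] == pytest.approx(0.5)


@st.composite
def two_group_samples(draw):
    n = draw(st.integers(3, 8))
    times = draw(st.lists(st.floats(0.2, 9.0), min_size=n, max_size=n, unique=True))
    events = draw(st.lists(st.integers(0, 1), min_size=n, max_size=n))
    g = draw(st.lists(st.integers(0, 1), min_size=n, max_size=n))
    return times, events, g


@given(two_group_samples())
def test_two_group_aalen_is_groupwise_nelson_aalen(data):
    """B1 equals the difference of group-wise Nelson-Aalen estimators and B0
    the reference group's, wherever the at-risk design has full rank."""
    times, events, g = data
    times, events, g = np.asarray(times), np.asarray(events), np.asarray(g, float)
    if events.sum() == 0 or len(set(g)) < 2:
        return
    s = make_sample(times, events, g=g)
    try:
        fit = hs.fit_aalen(s, ["g"])
    except hs.SurvivalDataError:
        return
    na0 = hs.nelson_aalen(s.subset(g == 0))
    na1 = hs.nelson_aalen(s.subset(g == 1))
    for j, t in enumerate(fit.times):
        # full-rank requires both groups at risk at every prior event time
        assert fit.cumulative["intercept"].iloc[j] == pytest.approx(na0(t), abs=1e-10)
        assert fit.cumulative["g"].iloc[j] == pytest.approx(na1(t) - na0(t), abs=1e-10)


def test_aalen_truncates_at_rank_deficiency():
    # group 1 exits at t=1.5; later events leave a single-group design
    s = make_sample([1.0, 1.5, 2.0, 3.0], [1, 0, 1, 1], g=[0.0, 1.0, 0.0, 0.0])
    fit = hs.fit_aalen(s, ["g"])
    assert fit.truncated and fit.last_estimable_time == 1.0


def test_aalen_rank_deficient_at_first_event_is_error():
    s = make_sample([1.0, 2.0, 3.0], [1, 1, 1], c=[1.0, 1.0, 1.0])
    with pytest.raises(hs.SurvivalDataError):
        hs.fit_aalen(s, ["c"])


def test_negative_cumulative_effects_are_legal():
    scn = hs.SimScenario(
        n=800, family="additive", baseline=0.5,
        covariates={"z": ("bernoulli", 0.5)},
        effects={"z": hs.EffectSpec(-0.25)}, censoring_time=4.0,
    )
    s = hs.simulate_additive(scn, seed=3)
    fit = hs.fit_aalen(s, ["z"])
    assert fit.cumulative["z"].iloc[-1] < 0  # protective effect, no error


def test_aalen_requires_unique_event_times():
    s = make_sample([1.0, 1.0, 2.0], [1, 1, 0])
    with pytest.raises(hs.TiedTimesError):
        hs.fit_aalen(s, [])


def test_aalen_matches_r_aareg_increments(two_group, tmp_path):
    """Independent oracle: survival::aareg produces the same least-squares
    increments at the event times it reports."""
    rscript = tmp_path / "chk.R"
    rscript.write_text(
        "suppressMessages(library(survival))\n"
        "d <- data.frame(time=c(1,3,2,2.9), status=c(1,0,1,1), g=c(0,0,1,1))\n"
        "f <- aareg(Surv(time,status)~g, data=d)\n"
        "cat(jsonlite::toJSON(list(times=f$times, coef=f$coefficient), digits=12))\n"
    )
    try:
        out = subprocess.run(
            ["Rscript", str(rscript)], capture_output=True, text=True, timeout=120
        )
    except FileNotFoundError:
        pytest.skip("Rscript not available")
    ref = json.loads(out.stdout)
    fit = hs.fit_aalen(two_group, ["g"])
    inc = np.diff(np.vstack([np.zeros(2), fit.cumulative.to_numpy()]), axis=0)
    for rt, rc in zip(ref["times"], ref["coef"]):
        j = int(np.flatnonzero(np.isclose(fit.times, rt))[0])
        assert inc[j] == pytest.approx(rc, abs=1e-10)


def test_constant_alpha_recovery():
    scn = hs.SimScenario(
        n=4000, family="additive", baseline=0.3,
        covariates={"z": ("bernoulli", 0.5)},
        effects={"z": hs.EffectSpec(0.2)}, censoring_time=5.0,
    )
    s = hs.simulate_additive(scn, seed=11)
    fit = hs.fit_aalen(s, ["z"])
    for t in (1.5, 2.5, 3.5):
        j = np.searchsorted(fit.times, t)
        slope = fit.cumulative["z"].iloc[j] / fit.times[j]
        assert abs(slope - 0.2) / 0.2 < 0.25


# ---------------------------------------------------------------------------
# Lin-Ying estimator
# ---------------------------------------------------------------------------


def test_lin_gamma_recovery(additive_sample):
    fit = hs.fit_lin(additive_sample, ["z"])
    se = fit.standard_errors()["z"]
    assert abs(fit.gamma["z"] - 0.2) < 3 * se


def test_lin_empty_design_baseline_is_nelson_aalen(additive_sample):
    fit = hs.fit_lin(additive_sample, [])
    na = hs.nelson_aalen(additive_sample)
    tq = np.quantile(additive_sample.times, [0.25, 0.5, 0.75])
    assert fit.baseline(tq) == pytest.approx(na(tq), abs=1e-10)


def test_lin_baseline_drift_identity(additive_sample):
    """Baseline plus the integrated xbar' gamma drift recovers the raw
    Nelson-Aalen-type jump sum."""
    fit = hs.fit_lin(additive_sample, ["z"])
    tau = float(fit.baseline.jump_times[-1])
    t = np.sort(additive_sample.times)
    z = additive_sample.covariate("z")[np.argsort(additive_sample.times, kind="stable")]
    acc, prev = 0.0, 0.0
    for i, tt in enumerate(t):
        if tt > tau:
            break
        acc += z[i:].mean() * fit.gamma["z"] * (tt - prev)
        prev = tt
    na = hs.nelson_aalen(additive_sample)
    assert fit.baseline(tau) + acc == pytest.approx(na(tau), abs=1e-8)


def test_lin_singular_design_error():
    s = make_sample([1.0, 2.0, 3.0], [1, 1, 0], c=[1.0, 1.0, 1.0])
    with pytest.raises(hs.SurvivalDataError):
        hs.fit_lin(s, ["c"])


def test_lin_gamma_null_effect_ci_covers_zero():
    cover = 0
    for r in range(60):
        scn = hs.SimScenario(
            n=500, family="additive", baseline=0.4,
            covariates={"z": ("bernoulli", 0.5)},
            effects={"z": hs.EffectSpec(0.0)}, censoring_time=4.0,
        )
        s = hs.simulate_additive(scn, seed=900 + r)
        fit = hs.fit_lin(s, ["z"])
        se = fit.standard_errors()["z"]
        cover += abs(fit.gamma["z"]) <= 1.96 * se
    assert cover / 60 >= 0.85


def test_lin_slope_matches_aalen_cumulative_slope(additive_sample):
    afit = hs.fit_aalen(additive_sample, ["z"])
    lfit = hs.fit_lin(additive_sample, ["z"])
    t, B = afit.times, afit.cumulative["z"].to_numpy()
    ls_slope = float(np.sum(t * B) / np.sum(t * t))  # through-origin LS line
    assert ls_slope == pytest.approx(lfit.gamma["z"], abs=0.05)


# ---------------------------------------------------------------------------
# constant-effect check
# ---------------------------------------------------------------------------


def test_constant_effect_verdict_constant(additive_sample):
    afit = hs.fit_aalen(additive_sample, ["z"])
    lfit = hs.fit_lin(additive_sample, ["z"])
    chk = hs.constant_effect_check(afit, lfit, "z")
    assert chk.constant and chk.coverage_fraction >= 0.95


def test_constant_effect_verdict_early_only():
    scn = hs.SimScenario(
        n=1500, family="additive", baseline=0.3,
        covariates={"z": ("bernoulli", 0.5)},
        effects={"z": hs.EffectSpec(((0.0, 0.6), (0.5, 0.6), (0.50001, 0.0), (4.0, 0.0)))},
        censoring_time=4.0,
    )
    s = hs.simulate_additive(scn, seed=23)
    afit = hs.fit_aalen(s, ["z"])
    lfit = hs.fit_lin(s, ["z"])
    chk = hs.constant_effect_check(afit, lfit, "z")
    assert not chk.constant


def test_constant_effect_degenerate_self_comparison(additive_sample):
    lfit = hs.fit_lin(additive_sample, ["z"])
    afit = hs.fit_aalen(additive_sample, ["z"])
    # zero-width band: compare the Lin line against itself
    afit.cumulative["z"] = lfit.gamma["z"] * afit.times
    afit.variance["z"] = 0.0
    chk = hs.constant_effect_check(afit, lfit, "z")
    assert chk.coverage_fraction == 1.0


# ---------------------------------------------------------------------------
# martingale residual processes
# ---------------------------------------------------------------------------


def test_mrp_saturated_categorical_is_exactly_zero(additive_sample):
    fit = hs.fit_aalen(additive_sample, ["z"])
    strata = dict(zip(additive_sample.subject_ids, additive_sample.covariate("z").astype(int)))
    mrp = hs.martingale_residual_process(fit, strata, resamples=150, seed=1)
    for g in mrp.strata:
        assert np.max(np.abs(mrp.observed[g])) < 1e-9
    test = hs.mrp_chisq_test(mrp)
    assert (test["p"] == 1.0).all()


def test_mrp_starts_at_zero_and_is_deterministic(additive_sample):
    scn = hs.SimScenario(
        n=400, family="additive", baseline=0.3,
        covariates={"z": ("uniform", 0.0, 1.0)},
        effects={"z": hs.EffectSpec(0.3)}, censoring_time=4.0,
    )
    s = hs.simulate_additive(scn, seed=2)
    fit = hs.fit_aalen(s, ["z"])
    lab, _ = hs.strata_by_quantiles(s.covariate("z"), 4)
    strata = dict(zip(s.subject_ids, lab))
    a = hs.martingale_residual_process(fit, strata, resamples=120, seed=9)
    b = hs.martingale_residual_process(fit, strata, resamples=120, seed=9)
    for g in a.strata:
        assert np.array_equal(a.lower[g], b.lower[g])
    # strata partition the sample: processes sum to zero at all times
    total = sum(a.observed[g] for g in a.strata)
    assert np.max(np.abs(total)) < 1e-9


def test_mrp_resamples_floor():
    s = make_sample([1.0, 2.0, 3.0], [1, 1, 0], g=[0.0, 1.0, 0.0])
    fit = hs.fit_aalen(s, [])
    with pytest.raises(ValueError):
        hs.martingale_residual_process(fit, dict(zip(s.subject_ids, [0, 1, 0])), resamples=50)


def test_mrp_zero_event_stratum_flagged():
    s = make_sample([1.0, 2.0, 3.0, 4.0], [1, 1, 0, 0], g=[0.0, 0.0, 1.0, 1.0])
    fit = hs.fit_aalen(s, [])
    with pytest.warns(UserWarning, match="zero events"):
        mrp = hs.martingale_residual_process(
            fit, dict(zip(s.subject_ids, [0, 0, 1, 1])), resamples=100, seed=0
        )
    assert mrp.low_information == [1]


def test_mrp_detects_nonlinear_functional_form():
    scn = hs.SimScenario(
        n=2000, family="additive", baseline=0.35,
        covariates={"z": ("normal", 0.0, 1.0)},
        effects={"z": hs.EffectSpec(0.25, hs.FunctionalForm("scaled_exponential", c=1.0))},
        censoring_time=3.0,
    )
    s = hs.simulate_additive(scn, seed=77)
    fit = hs.fit_aalen(s, ["z"])  # misspecified: linear in z
    lab, _ = hs.strata_by_quantiles(s.covariate("z"), 4)
    mrp = hs.martingale_residual_process(fit, dict(zip(s.subject_ids, lab)), resamples=200, seed=3)
    test = hs.mrp_chisq_test(mrp)
    assert test.loc["global", "p"] < 0.05
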