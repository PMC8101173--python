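import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import hazstrat as hs

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_sample(times, events, **covariates) -> hs.SurvivalSample:
    df = pd.DataFrame(
        {"subject_id": np.arange(len(times)), "time": np.asarray(times, float),
         "event": np.asarray(events, int), **covariates}
    )
    return hs.SurvivalSample(df)


@pytest.fixture
def three_subject():
    """The analytic worked example: beta-hat = -(1/2) ln 2."""
    return make_sample([1.0, 2.0, 3.0], [1, 1, 0], x=[1.0, 0.0, 1.0])


@pytest.fixture
def two_group():
    """Two-group additive example with closed-form Aalen solution."""
    return make_sample([1.0, 3.0, 2.0, 2.9], [1, 0, 1, 1], g=[0.0, 0.0, 1.0, 1.0])


@pytest.fixture(scope="session")
def ph_sample():
    """Moderate proportional-hazards dataset, one normal covariate."""
    scn = hs.SimScenario(
        n=600, family="multiplicative", baseline=0.5,
        covariates={"z": ("normal", 0.0, 1.0)},
        effects={"z": hs.EffectSpec(0.7)}, censoring_time=3.0,
    )
    return hs.simulate_multiplicative(scn, seed=42)


@pytest.fixture(scope="session")
def additive_sample():
    """Constant additive effect of a binary covariate."""
    scn = hs.SimScenario(
        n=1500, family="additive", baseline=0.3,
        covariates={"z": ("bernoulli", 0.5)},
        effects={"z": hs.EffectSpec(0.2)}, censoring_time=5.0,
    )
    return hs.simulate_additive(scn, seed=43)
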