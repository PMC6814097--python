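import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ltcmsm as L

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def structure():
    return L.TransitionStructure.default()


@pytest.fixture(scope="session")
def calibrated_params(structure):
    return L.IntensityParameters.from_rates(structure, L.CALIBRATED_RATES)


@pytest.fixture(scope="session")
def calibrated_Q(calibrated_params):
    return L.build_generator(calibrated_params)


@pytest.fixture(scope="session")
def small_cohort():
    """A 400-subject exactly observed cohort under the calibrated defaults."""
    tm = L.default_true_model(n=400, seed=11)
    trajectories, cov = L.simulate_cohort(tm)
    data = L.observe_cohort(trajectories, cov, tm.scheme, tm.structure, tm.horizon)
    return tm, trajectories, data


def random_progressive_generator(rng, structure):
    """A random valid generator on the default progressive structure."""
    rates = {
        (i + 1, j + 1): rng.uniform(0.01, 0.5) for i, j in structure.transitions
    }
    params = L.IntensityParameters.from_rates(structure, rates)
    return L.build_generator(params)
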