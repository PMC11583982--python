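import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from natfert.simulate import ParameterVector, SimulationConfig, simulate_cohort

# property tests must not flake on a loaded single-CPU box
settings.register_profile(
    "ci", deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def theta():
    return ParameterVector(mu_m=22.0, sigma_m=3.0, phi1=0.4, phi2=0.2, delta=8.0)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_women=300, seed=7, age_grid=tuple(range(15, 50)))


@pytest.fixture(scope="session")
def small_cohort(theta, small_config):
    return simulate_cohort(theta, small_config)
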