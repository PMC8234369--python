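import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import decaval as dv

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def true_model() -> dv.CoefficientSet:
    return dv.synthetic_decapret_model()


@pytest.fixture(scope="session")
def default_config() -> dv.SimulationConfig:
    return dv.SimulationConfig(seed=20160101)


@pytest.fixture(scope="session")
def cohort_273(default_config) -> dv.CohortTable:
    """One default-sized synthetic cohort, shared across tests."""
    return dv.generate_cohort(default_config)


@pytest.fixture(scope="session")
def cohort_5000() -> dv.CohortTable:
    from dataclasses import replace

    cfg = dv.SimulationConfig(n_patients=5000, seed=424242)
    return dv.generate_cohort(cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
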