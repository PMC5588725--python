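import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from maxsnippet import (
    FeatureEncoding,
    FitConfig,
    encode_cohort,
    fit,
)
from maxsnippet.simulate import SimConfig, simulate_cohort

settings.register_profile(
    "suite",
    derandomize=True,
    database=None,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


def tiny_sim_config(seed=7, **overrides):
    """A small, quickly separable cohort for unit-scale fitting tests."""
    kwargs = dict(
        n_cases=4,
        n_controls=4,
        cdr3s_per_patient=(20, 20),
        motif_prevalence=1.0,
        plants_per_carrier=(2, 2),
        seed=seed,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


@pytest.fixture(scope="session")
def tiny_cohort():
    return simulate_cohort(tiny_sim_config())


@pytest.fixture(scope="session")
def tiny_features(tiny_cohort):
    cohort, _truth = tiny_cohort
    return encode_cohort(cohort, FeatureEncoding("atchley", 6))


@pytest.fixture(scope="session")
def tiny_fit(tiny_cohort, tiny_features):
    cohort, _truth = tiny_cohort
    config = FitConfig(n_restarts=30, n_iterations=1500, seed=7)
    return fit(tiny_features, cohort.labels, config)
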