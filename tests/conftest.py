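import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import apcmort as m

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def grid():
    return m.default_grid()


@pytest.fixture(scope="session")
def std(grid):
    return m.restrict_weights(m.who_world_standard(), grid)


@pytest.fixture(scope="session")
def male_low_truth():
    return m.default_scenario("male", "low")


@pytest.fixture(scope="session")
def male_low_counts(male_low_truth):
    return m.simulate_grid_counts(male_low_truth, seed=101)


@pytest.fixture(scope="session")
def small_mcmc():
    """Reduced-budget sampler settings used by the slower model tests."""
    return m.MCMCConfig(
        n_chains=3,
        n_keep_total=1500,
        min_burn_in=600,
        max_burn_in=3000,
        check_every=300,
        seed=11,
    )


@pytest.fixture(scope="session")
def male_low_posterior(male_low_counts, small_mcmc):
    spec = m.APCModelSpec(grid=male_low_counts.grid)
    return m.sample_posterior(male_low_counts, spec, small_mcmc)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
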