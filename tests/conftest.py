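import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def small_dataset():
    """A small clean two-condition dataset with known generating parameters."""
    from rezddm import PopulationParams, draw_individuals, generate_dataset

    rng = np.random.default_rng(11)
    pop = PopulationParams(
        mu_nu=1.0, beta=0.4, sigma2_nu=0.75,
        mu_alpha=3.0, sigma2_alpha=0.5,
        mu_tau=0.3, sigma2_tau=0.1,
    )
    ind = draw_individuals(pop, 8, rng)
    data = generate_dataset(ind, 40, rng)
    return pop, ind, data
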