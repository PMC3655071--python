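import random

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return random.Random(20240901)


@pytest.fixture(scope="session")
def small_study():
    """A small simulated experiment shared across read-level tests."""
    from depthsat.synthetic_data import simulate_study

    return simulate_study(n_genes=20, n_kog=12, seed=7)
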