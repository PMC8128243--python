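import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_exp1_dataset():
    """Four-participant experiment-1 cohort, reused by analysis tests."""
    from vaelab.observer import simulate_dataset

    return simulate_dataset(1, 4, rng=np.random.default_rng(99))
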