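import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

from nmfkit import SyntheticSpec, make_synthetic


@pytest.fixture(scope="session")
def small_data():
    """Well-separated 3-group dataset, modest size, fixed seed."""
    return make_synthetic(SyntheticSpec(n=60, p=18, r=3, group_sizes=[8, 4, 6],
                                        noise_sd=0.05, rng_seed=7))


@pytest.fixture(scope="session")
def noiseless_data():
    """Exact X = W0 @ H0 (rank 3), for recovery checks."""
    return make_synthetic(SyntheticSpec(n=60, p=18, r=3, group_sizes=[8, 4, 6],
                                        noise_sd=0.0, rng_seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
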