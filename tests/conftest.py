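import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_gray(rng):
    """Random 16x16 8-bit frame for brute-force oracle comparisons."""
    return rng.integers(0, 256, size=(16, 16), dtype=np.uint8)
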