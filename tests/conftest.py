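import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from glycoimmune.datagen import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_bundle():
    """Default-condition synthetic bundle shared by read-only tests."""
    return simulate_dataset(SimConfig(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
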