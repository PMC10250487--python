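import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """Five-class two-block dataset at reduced size, shared read-only."""
    from salmofuse import synthetic_data as sd

    return sd.make_dataset(sd.SimConfig(n_per_class=20, seed=11))
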