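import numpy as np
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
    return np.random.default_rng(20_240_917)


@pytest.fixture
def small_genome():
    """A 20 kb random genome; 20-mers are unique with overwhelming probability."""
    from gefcall import generate_genome

    return generate_genome(20_000, 0.5, seed=7)
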