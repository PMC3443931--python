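import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=200,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def probit_sample():
    """3000 trials from a cumulative Gaussian with PSE 10 and threshold 50."""
    from scipy.special import ndtr

    gen = np.random.default_rng(1234)
    x = gen.normal(0.0, 100.0, 3000)
    y = (gen.random(3000) < ndtr((x - 10.0) / 50.0)).astype(float)
    return x, y
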