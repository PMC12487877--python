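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
    return np.random.default_rng(1234)


@pytest.fixture
def gaussian_frame():
    """Single isotropic Gaussian spot (sigma=2) on a 41x41 frame."""

    def make(cx=20.0, cy=20.0, sigma=2.0, amplitude=100.0, shape=(41, 41), offset=0.0):
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(np.float64)
        return amplitude * np.exp(-(((xx - cx) ** 2) + (yy - cy) ** 2) / (2.0 * sigma**2)) + offset

    return make
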