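import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from frapkit.simulate import SimulationParams, simulate_frap_movie


def fast_params(**overrides) -> SimulationParams:
    """Small, quick simulation geometry for unit tests."""
    defaults = dict(
        image_size=(64, 64),
        nucleus_center=(32.0, 32.0),
        nucleus_radius=20.0,
        bleach_center=(32.0, 32.0),
        bleach_radius=4.0,
        n_prebleach=10,
        n_postbleach=60,
        seed=0,
    )
    defaults.update(overrides)
    return SimulationParams(**defaults)


@pytest.fixture
def params_fast():
    return fast_params()


@pytest.fixture
def movie_fast(params_fast):
    return simulate_frap_movie(params_fast)


def smooth_image(shape=(64, 64), seed=0, sigma=2.0) -> np.ndarray:
    """Band-limited random test image (periodic smoothing for Fourier shifts)."""
    rng = np.random.default_rng(seed)
    return gaussian_filter(rng.normal(size=shape), sigma, mode="wrap")
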