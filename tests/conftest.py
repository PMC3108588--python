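import numpy as np
import pytest

from glideassay import ImagingParams, MotilityParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def quiet_motility():
    """Deterministic straight-line gliding: all noise and rates zero."""
    return MotilityParams(speed_mean=1000.0, speed_jitter_sd=0.0, brownian_end_sd=0.0,
                          pause_on_rate=0.0, pause_off_rate=0.0, detach_rate=0.0,
                          path_turn_sd=0.0, length_range_um=(5.0, 5.0))


@pytest.fixture
def small_imaging():
    return ImagingParams(field_size=(256, 256), dead_pixel_fraction=0.0)


def straight_mask(shape=(20, 60), rows=slice(8, 11), cols=slice(10, 50)):
    m = np.zeros(shape, dtype=bool)
    m[rows, cols] = True
    return m


def ring_mask(size=32, r_outer=10, r_inner=6):
    rr, cc = np.mgrid[0:size, 0:size]
    d = np.hypot(rr - size / 2, cc - size / 2)
    return (d < r_outer) & (d > r_inner)
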