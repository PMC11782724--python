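import numpy as np
import pytest

from lungboot import CARDIAC, RESPIRATORY, CineSeries, make_phantom, simulate_cine
from lungboot.phantom import PhantomConfig


@pytest.fixture(scope="session")
def phantom32():
    return make_phantom(PhantomConfig(grid_shape=(32, 32)), seed=7)


@pytest.fixture(scope="session")
def phantom64():
    return make_phantom(seed=1)


@pytest.fixture(scope="session")
def quiet_phantom32():
    """Noise-free 32x32 phantom for exact-recovery checks."""
    return make_phantom(PhantomConfig(grid_shape=(32, 32), noise_sigma=0.0), seed=7)


@pytest.fixture(scope="session")
def resp_series32(phantom32):
    return simulate_cine(phantom32, RESPIRATORY, n_avg=6, seed=3)


@pytest.fixture(scope="session")
def card_series32(phantom32):
    return simulate_cine(phantom32, CARDIAC, n_avg=6, seed=4)


def make_series(data, kind=RESPIRATORY, duration=4000.0, **kw):
    """Small helper: wrap a raw array as a cine series."""
    return CineSeries(
        data=np.asarray(data, dtype=float), cycle_kind=kind,
        cycle_duration_ms=duration, **kw,
    )
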