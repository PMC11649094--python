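import numpy as np
import pytest

from hypercut import Hypercube


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cube(rng):
    """A random 16x16 cube with 5 bands on a coarse wavelength grid."""
    data = rng.uniform(0.05, 0.95, size=(16, 16, 5))
    return Hypercube(data=data, wavelengths_nm=[400, 550, 700, 850, 1000])


@pytest.fixture
def tiny_wavelengths():
    return np.arange(400.0, 1001.0, 20.0)  # 31 bands spanning 600 nm
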