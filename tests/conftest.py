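import numpy as np
import pytest

from morphconnect import make_surface_mesh


@pytest.fixture(scope="session")
def ico2():
    """162-vertex icosphere, the small cortical-surface stand-in."""
    return make_surface_mesh(2)


@pytest.fixture(scope="session")
def ico3():
    """642-vertex icosphere for smoothing-width calibration checks."""
    return make_surface_mesh(3)


@pytest.fixture()
def rng():
    return np.random.default_rng(20121120)


def translating_blob(shift: float, size: int = 64, width: float = 6.0, amp: float = 0.8):
    """A single smooth Gaussian blob shifted along x (analytic fixture)."""
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    c = size / 2.0
    return amp * np.exp(-(((xx - c - shift) ** 2) + ((yy - c) ** 2)) / (2 * width**2))
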