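import numpy as np
import pytest

import retseg
from retseg.io import FovMask, GrayImage


@pytest.fixture(scope="session")
def default_phantom():
    """Class-3 style phantom: vessels + gradient + noise + pathology."""
    spec = retseg.PhantomSpec(seed=1, pathology_blobs=2)
    img, truth = retseg.generate_phantom(spec)
    return spec, img, truth


@pytest.fixture(scope="session")
def two_texture_phantom():
    """Vessel-free half-fine/half-coarse noise phantom with partition truth."""
    spec = retseg.PhantomSpec(
        seed=2, n_vessels=0, pathology_blobs=0, illum_gradient=0.0
    )
    img, truth = retseg.generate_phantom(spec)
    return spec, img, truth


@pytest.fixture()
def gaussian_ridge():
    """Horizontal bright ridge of Gaussian cross-section (sigma_v = 2)."""
    H, W = 64, 96
    yy = np.mgrid[0:H, 0:W][0]
    return GrayImage(np.exp(-((yy - 32) ** 2) / (2 * 2.0**2))), 32


def full_fov(shape):
    return FovMask(np.ones(shape, dtype=bool))
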