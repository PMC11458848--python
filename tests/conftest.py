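import numpy as np
import pytest

from radrep.datatypes import ImageVolume, ROIMask


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240)


def random_level_grid(rng, max_side=6, max_levels=5):
    """A random small discretized grid with a random (non-empty) mask."""
    shape = tuple(rng.integers(2, max_side + 1, size=3))
    levels = rng.integers(1, max_levels + 1, size=shape)
    mask = rng.random(shape) < 0.7
    if not mask.any():
        mask[tuple(rng.integers(0, s) for s in shape)] = True
    return levels.astype(np.int64), mask


@pytest.fixture(scope="session")
def sphere_case():
    """A 30 mm textured sphere phantom at 1 mm isotropic spacing."""
    g = np.random.default_rng(7)
    shape = (40, 40, 40)
    zz, yy, xx = np.indices(shape)
    c = 19.5
    mask = (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= 15.0**2
    img = 40.0 + 25.0 * g.normal(size=shape)
    return ImageVolume(img), ROIMask(mask)


@pytest.fixture(scope="session")
def small_blob_case():
    """A small ellipsoid ROI for fast full extractions."""
    g = np.random.default_rng(11)
    shape = (28, 28, 28)
    zz, yy, xx = np.indices(shape)
    c = 13.5
    mask = ((zz - c) / 8.0) ** 2 + ((yy - c) / 7.0) ** 2 + ((xx - c) / 6.0) ** 2 <= 1.0
    img = 50.0 + 30.0 * g.normal(size=shape)
    return ImageVolume(img), ROIMask(mask)
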