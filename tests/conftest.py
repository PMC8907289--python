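import numpy as np
import pytest

from duograde.imgio import Volume3D
from duograde.phantom import PhantomConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """Phantom config on a 32^3 grid, fast enough for per-test generation."""
    return PhantomConfig(
        grid_shape=(32, 32, 32), tumor_radius_range_mm=(3.0, 5.5), seed=7
    )


@pytest.fixture
def unit_affine():
    return np.eye(4)


def make_volume(values, affine=None, role="T1CE"):
    if affine is None:
        affine = np.eye(4)
    return Volume3D(np.asarray(values), affine, role)


def make_sphere_mask(shape, center, radius_vox, affine=None):
    coords = np.meshgrid(*(np.arange(s, dtype=float) for s in shape), indexing="ij")
    dist2 = sum((c - mu) ** 2 for c, mu in zip(coords, center))
    mask = (dist2 <= radius_vox**2).astype(np.uint8)
    return make_volume(mask, affine, "MASK")
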