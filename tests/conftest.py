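"""Shared fixtures: small synthetic volumes and fast phantoms.

Everything is generated at test time from fixed seeds; the `fast` phantom
grid (32^3) keeps registration-heavy tests quick while preserving the
clinical voxel size, frame count and VENC.
"""

import numpy as np
import pytest
from scipy import ndimage

from flow4d.phantom import PhantomSpec, default_meta, make_phantom

FAST_SHAPE = (32, 32, 32)


@pytest.fixture(scope="session")
def blob_image():
    """Smooth multi-blob 32^3 test image with nonuniform structure."""
    rng = np.random.default_rng(0)
    shape = FAST_SHAPE
    grid = np.stack(np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"),
                    axis=-1).astype(float)
    img = np.zeros(shape)
    for _ in range(10):
        c = rng.uniform(6, 26, 3)
        r = rng.uniform(2, 5)
        img += np.exp(-np.sum((grid - c) ** 2, axis=-1) / (2 * r ** 2))
    return ndimage.gaussian_filter(img, 1.0)


@pytest.fixture(scope="session")
def textured_blob_image(blob_image):
    """Blob image with internal intensity texture, like a PC-MRA's speckle.

    Flat-interior objects leave the displacement unobservable inside
    (aperture problem); texture makes the recovered field testable
    throughout the object support.
    """
    rng = np.random.default_rng(3)
    tex = ndimage.gaussian_filter(rng.normal(size=FAST_SHAPE), 1.5)
    return blob_image * (1.0 + 0.4 * tex / np.abs(tex).max())


@pytest.fixture(scope="session")
def smooth_random_image():
    """Band-limited random volume: structure in every direction."""
    rng = np.random.default_rng(7)
    img = ndimage.gaussian_filter(rng.normal(size=FAST_SHAPE), 5.0)
    return (img - img.min()) / (img.max() - img.min())


@pytest.fixture(scope="session")
def sinusoid_field():
    """Smooth sinusoidal displacement field, 2-voxel peak amplitude.

    Each component varies sinusoidally along another axis (wavelength 64
    voxels), giving a shearing, everywhere-smooth deformation.
    """
    shape = FAST_SHAPE
    grid = np.stack(np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"),
                    axis=-1).astype(float)
    d = np.zeros(shape + (3,))
    for c in range(3):
        d[..., c] = 2.0 * np.sin(2 * np.pi * grid[..., (c + 1) % 3] / 64.0)
    return d


@pytest.fixture(scope="session")
def fast_phantom():
    """Straight-tube pulsatile phantom on the fast 32^3 grid."""
    spec = PhantomSpec(grid_shape=FAST_SHAPE, grid=default_meta())
    return make_phantom(spec)


@pytest.fixture(scope="session")
def moving_phantom():
    """Straight tube with 2 mm bulk sinusoidal motion (fast grid)."""
    spec = PhantomSpec(grid_shape=FAST_SHAPE, grid=default_meta(),
                       motion_amplitude=2.0)
    return make_phantom(spec)
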