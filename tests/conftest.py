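import numpy as np
import pytest

from atlasmaker.core import BinaryMask, VolumeStack, VoxelSpacing
from atlasmaker.phantom import PhantomParams, make_neural_tube_phantom

UNIT = VoxelSpacing(1.0, 1.0, 1.0)


@pytest.fixture(scope="session")
def unit_spacing():
    return UNIT


@pytest.fixture(scope="session")
def phantom_default():
    """One 64^3 phantom at default (noisy) settings, shared across tests."""
    return make_neural_tube_phantom(seed=0)


@pytest.fixture(scope="session")
def phantom_clean():
    """Noise-free phantom: thresholding channel 1 recovers the domain exactly."""
    return make_neural_tube_phantom(seed=0, params=PhantomParams(noise_sd=0.0))


def random_mask(shape, rng, p=0.5, spacing=UNIT):
    return BinaryMask(rng.random(shape) < p, spacing)


def digitized_sphere(radius, grid=None, spacing=UNIT, center=None):
    """Voxelized ball of the given radius (in voxels) on an isotropic grid."""
    n = grid or int(2 * radius + 8)
    c = center if center is not None else (n - 1) / 2.0
    zz, yy, xx = np.ogrid[:n, :n, :n]
    ball = (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= radius**2
    return BinaryMask(ball, spacing)
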