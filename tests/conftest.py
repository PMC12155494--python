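import numpy as np
import pytest

from petacpurify.grid import VoxelGrid
from petacpurify.phantoms import make_phantom, simulate_pair


@pytest.fixture(scope="session")
def phantom_small():
    """One default-geometry subject on a compact grid."""
    return make_phantom(7, grid_shape=(32, 32, 40), geometry_jitter=0.1)


@pytest.fixture(scope="session")
def clean_pair_noiseless(phantom_small):
    return simulate_pair(phantom_small, "none", noise_scale=0.0, seed=1)


@pytest.fixture(scope="session")
def noisy_pair(phantom_small):
    return simulate_pair(phantom_small, "none", noise_scale=0.05, seed=2)


@pytest.fixture(scope="session")
def halo_pair(phantom_small):
    return simulate_pair(phantom_small, "halo", noise_scale=0.05, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_grid_pair(rng, shape=(6, 6, 6), spacing=(4.07, 4.07, 3.0)):
    a = rng.random(shape).astype(np.float32) + 0.1
    b = rng.random(shape).astype(np.float32) + 0.1
    return VoxelGrid(a, spacing), VoxelGrid(b, spacing)
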