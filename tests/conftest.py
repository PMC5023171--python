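import numpy as np
import pytest

from spontaffect import synthetic_data as syn


@pytest.fixture(scope="session")
def flat_weights():
    """Sparse disjoint weight maps on a flat 100-voxel grid."""
    return syn.generate_weight_maps(n_voxels=100, sparsity=0.1, overlap=0.0, seed=1)


@pytest.fixture(scope="session")
def small_weights():
    """Weight maps on a small 3D grid (~136 in-mask voxels)."""
    grid = syn.default_grid((6, 6, 6), radius=3.2)
    return syn.generate_weight_maps(grid=grid, sparsity=0.1, seed=0)


@pytest.fixture(scope="session")
def default_weights():
    """Weight maps on the default 10×10×10 grid (~672 in-mask voxels)."""
    return syn.generate_weight_maps(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
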