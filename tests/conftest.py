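import numpy as np
import pytest

from connclust import MaskedGrid, pearson_connectivity


@pytest.fixture
def rng():
    return np.random.default_rng(20240606)


@pytest.fixture
def grid2d():
    return MaskedGrid(np.ones((6, 6), dtype=bool), voxel_size_mm=(4.0, 4.0))


@pytest.fixture
def grid3d():
    return MaskedGrid(np.ones((4, 4, 4), dtype=bool),
                      voxel_size_mm=(4.0, 4.0, 4.0))


@pytest.fixture
def paired_matrices(rng):
    """Factory for seeded random paired connectivity matrices."""

    def make(n_subjects, n_voxels, T=30, seed=None):
        local = np.random.default_rng(seed) if seed is not None else rng
        mats_a, mats_b = [], []
        for _ in range(n_subjects):
            mats_a.append(
                pearson_connectivity(local.standard_normal((n_voxels, T))).values
            )
            mats_b.append(
                pearson_connectivity(local.standard_normal((n_voxels, T))).values
            )
        return mats_a, mats_b

    return make
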