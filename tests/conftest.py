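import logging

import numpy as np
import pandas as pd
import pytest

from topomaps import grid_io, synthetic
from topomaps.grid_io import ProteinMeta, ProteinQuantMatrix, VoxelGrid

# per-protein isolated-voxel drops are routine on sparse synthetic data
logging.getLogger("topomaps").setLevel(logging.ERROR)


def make_grid(n_rows: int, n_cols: int, voxel_side: float = 1.0, **kwargs) -> VoxelGrid:
    positions = {
        grid_io.voxel_id(r, c): (r, c) for r in range(n_rows) for c in range(n_cols)
    }
    return VoxelGrid(n_rows, n_cols, voxel_side, positions, **kwargs)


def make_matrix(values, voxels=None, normalized=True, ids=None) -> ProteinQuantMatrix:
    arr = np.asarray(values, dtype=float)
    voxels = voxels or [f"v{i}" for i in range(arr.shape[1])]
    ids = ids or [f"P{i}" for i in range(arr.shape[0])]
    metas = [ProteinMeta(protein_group_id=i, gene_name=i) for i in ids]
    return ProteinQuantMatrix(
        pd.DataFrame(arr, index=ids, columns=voxels), metas, normalized=normalized
    )


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic dataset (16x16, 300 proteins), normalized."""
    m, grid, features, truth = synthetic.generate(seed=11)
    norm = grid_io.filter_min_voxels(grid_io.normalize(m))
    return norm, grid, features, truth


@pytest.fixture()
def grid_2x2():
    return make_grid(2, 2)


@pytest.fixture()
def grid_1x4():
    return make_grid(1, 4)
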