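import numpy as np
import pytest

from livervoi import Ellipsoid, PhantomSpec, VoxelGrid, generate_phantom
from livervoi.voi_geometry import SphereVOI, sphere_mask


def small_spec(**overrides) -> PhantomSpec:
    """A compact phantom (80x80x60) whose organs fit the reduced grid."""
    spec = PhantomSpec(
        shape=(80, 80, 60),
        liver=Ellipsoid((160.0, 160.0, 60.0), (60.0, 50.0, 40.0), 2.5),
        lung=Ellipsoid((160.0, 160.0, 110.0), (60.0, 50.0, 8.0), 0.5),
        hot_organs=(),
    )
    return spec.with_(**overrides)


@pytest.fixture(scope="session")
def phantom7():
    """Default phantom, seed 7: (grid, labels, truth)."""
    return generate_phantom(PhantomSpec(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_grid(values, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)):
    return VoxelGrid(values=np.asarray(values, dtype=float), spacing=spacing, origin=origin)


def brute_force_local_stats(grid, diameter_mm):
    """Per-voxel nested-loop definition of local mean/SD/CVv.

    The independent oracle: for every voxel, realize the spherical
    neighborhood with sphere_mask, clip to the grid, and apply the plain
    numpy definitions (sample SD, n-1). Mirrors the validity rules:
    neighborhoods of <2 voxels or nonpositive mean are invalid (+inf CVv).
    """
    shape = grid.shape
    mean = np.zeros(shape)
    sd = np.zeros(shape)
    cvv = np.full(shape, np.inf)
    valid = np.zeros(shape, dtype=bool)
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                center = grid.index_to_world((i, j, k))
                m = sphere_mask(grid, SphereVOI(tuple(center), diameter_mm))
                vals = grid.values[m]
                mu = float(np.mean(vals))
                s = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
                mean[i, j, k] = mu
                sd[i, j, k] = s
                if vals.size >= 2 and mu > 0:
                    valid[i, j, k] = True
                    cvv[i, j, k] = s / mu
    return mean, sd, cvv, valid
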