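import numpy as np
import pytest

from qam3d import LabelMask, VoxelGrid
from qam3d.phantom import PhantomSpec, make_phantom_case, sphere_pair_grid


@pytest.fixture(scope="session")
def concentric_case_s1():
    """Concentric r=10 / R=15 sphere pair at 1 mm spacing (fast)."""
    return make_phantom_case(sphere_pair_grid(10.0, 15.0, 0.0, 1.0))


@pytest.fixture(scope="session")
def offset7_case_s05():
    """Offset d=7 sphere pair at 0.5 mm: analytic residual fraction 22.857%."""
    return make_phantom_case(sphere_pair_grid(10.0, 15.0, 7.0, 0.5))


@pytest.fixture(scope="session")
def halfspace_liver_case():
    """Concentric sphere pair with the tumor bisected by a planar liver capsule."""
    grid = sphere_pair_grid(10.0, 15.0, 0.0, 1.0).grid
    spec = PhantomSpec(
        grid=grid,
        tumor_center_mm=(0.0, 0.0, 0.0),
        ablation_center_mm=(0.0, 0.0, 0.0),
        tumor_radii_mm=(10.0, 10.0, 10.0),
        ablation_radii_mm=(15.0, 15.0, 15.0),
        liver_normal=(0.0, 0.0, 1.0),
        liver_offset_mm=0.0,
    )
    return make_phantom_case(spec)


@pytest.fixture()
def cube_mask():
    """4^3 solid cube centered in a 10^3 unit grid."""
    grid = VoxelGrid((10, 10, 10), (1.0, 1.0, 1.0))
    occ = np.zeros((10, 10, 10), dtype=bool)
    occ[3:7, 3:7, 3:7] = True
    return LabelMask(grid, occ, "cube")
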