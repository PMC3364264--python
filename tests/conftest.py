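import numpy as np
import pytest

from kinheart.generators import (
    CylinderSpec, SheetSpec, make_thick_cylinder, make_thick_sheet,
)
from kinheart.mesh import TetMesh

UNIT_TET_VERTS = np.array(
    [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
)


@pytest.fixture
def unit_tet() -> TetMesh:
    return TetMesh(UNIT_TET_VERTS.copy(), np.array([[0, 1, 2, 3]]))


@pytest.fixture(scope="session")
def small_cylinder():
    """Coarse benchmark cylinder (shared, treat as read-only)."""
    return make_thick_cylinder(
        CylinderSpec(n_radial=2, n_circumferential=12, n_axial=4)
    )


@pytest.fixture(scope="session")
def small_sheet():
    return make_thick_sheet(SheetSpec(n_x=4, n_y=2, n_z=4))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
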