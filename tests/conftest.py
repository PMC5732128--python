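import numpy as np
import pytest

from pinrecon.geometry import CameraGeometry, PinholeUnit, default_arc_geometry
from pinrecon.phantoms import VoxelGrid, uniform_air_density
from pinrecon.physics import PhysicsTables


@pytest.fixture(scope="session")
def tables():
    return PhysicsTables.default()


@pytest.fixture(scope="session")
def small_grid():
    """9^3 grid of 4-mm voxels (36-mm cube)."""
    return VoxelGrid(9, 4.0)


@pytest.fixture(scope="session")
def small_geometry():
    """Three-unit arc, standard distances."""
    return default_arc_geometry(K=3)


@pytest.fixture(scope="session")
def single_unit():
    """One pinhole-detector unit on the +z axis."""
    return PinholeUnit(theta=0.0, phi=0.0)


@pytest.fixture(scope="session")
def single_unit_geometry(single_unit):
    return CameraGeometry(units=(single_unit,))


@pytest.fixture(scope="session")
def air(small_grid):
    return uniform_air_density(small_grid)


@pytest.fixture()
def rng():
    return np.random.default_rng(20170)
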