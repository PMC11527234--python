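import numpy as np
import pytest

from asciflow import geometry as geo


@pytest.fixture(scope="session")
def cavity_spec():
    """Desk-resolution 2D cavity used across tests."""
    return geo.CavitySpec(mesh_size=0.015, z_ov=0.05)


@pytest.fixture(scope="session")
def cavity_mesh(cavity_spec):
    return geo.build_cavity_mesh(cavity_spec)


@pytest.fixture(scope="session")
def coarse_spec():
    """Very coarse cavity for fast solver-level tests."""
    return geo.CavitySpec(mesh_size=0.04, z_ov=0.05)


@pytest.fixture(scope="session")
def coarse_mesh(coarse_spec):
    return geo.build_cavity_mesh(coarse_spec)


@pytest.fixture()
def unit_square_mesh():
    x = np.linspace(0.0, 1.0, 5)
    return geo.structured_rectangle(x, x)


@pytest.fixture()
def unit_cube_mesh():
    x = np.linspace(0.0, 1.0, 4)
    return geo.structured_box(x, x, x)
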