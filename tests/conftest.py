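import numpy as np
import pytest

from celltaxis.fem import HexMesh
from celltaxis.geometry import init_spherical_cell


@pytest.fixture(scope="session")
def coarse_mesh():
    """Acceptance-scale substrate: 400x200x200 um, 10 um elements."""
    return HexMesh(400.0, 200.0, 200.0, 40, 20, 20)


@pytest.fixture(scope="session")
def gradient_modulus(coarse_mesh):
    """1 kPa at x=0 to 100 kPa at x=400 um, linear in x."""
    x = coarse_mesh.element_centroids[:, 0]
    return 1.0 + 99.0 * x / 400.0


@pytest.fixture()
def centered_ball(coarse_mesh):
    return init_spherical_cell(coarse_mesh, (200.0, 100.0, 100.0), 20.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
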