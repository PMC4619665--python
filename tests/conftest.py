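import numpy as np
import pytest

from vkreg.elasticity import MaterialParams, constitutive_matrix
from vkreg.mesh import NodalField, build_uniform_trimesh


@pytest.fixture
def material():
    return MaterialParams()


@pytest.fixture
def D(material):
    return constitutive_matrix(material)


@pytest.fixture
def small_mesh():
    """10x10-pixel domain, 4x4 nodes, 18 triangles."""
    return build_uniform_trimesh(10, 10, 4)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_displacement(mesh, rng, scale=0.3):
    return NodalField(rng.normal(scale=scale, size=(mesh.n_nodes, 2)))
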