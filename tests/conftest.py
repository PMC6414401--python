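import numpy as np
import pytest
import trimesh as _trimesh

from shapetraj.mesh_io import TriMesh


def icosphere(subdivisions=1, radius=1.0, scale=(1.0, 1.0, 1.0), centre=(0.0, 0.0, 0.0)):
    ico = _trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    v = np.asarray(ico.vertices) * np.asarray(scale, dtype=float) + np.asarray(
        centre, dtype=float
    )
    return TriMesh(v, np.asarray(ico.faces), name="icosphere")


@pytest.fixture
def unit_sphere():
    return icosphere(subdivisions=1)


@pytest.fixture
def ellipsoid():
    """Thalamus-scale ellipsoid (mm)."""
    return icosphere(subdivisions=1, scale=(11.0, 7.0, 6.0))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_small_mesh(rng, n_extra=0, scale=1.0):
    """A tetrahedron-based random mesh (4 + n_extra vertices)."""
    base_v = np.array(
        [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]]
    ) + 0.2 * rng.normal(size=(4, 3))
    base_t = np.array([[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]])
    return TriMesh(base_v * scale, base_t)
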