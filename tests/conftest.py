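import numpy as np
import pytest
import trimesh as _trimesh

from meshgat import TriangleMesh, make_dataset, build_feature_table
from meshgat.graph import build_graph


@pytest.fixture
def cube_mesh() -> TriangleMesh:
    """Unit cube: 8 vertices, 12 triangles, watertight."""
    box = _trimesh.creation.box(extents=(1.0, 1.0, 1.0))
    return TriangleMesh(np.asarray(box.vertices) + 0.5, np.asarray(box.faces))


@pytest.fixture
def tetra_mesh() -> TriangleMesh:
    """Unit right tetrahedron (0,0,0),(1,0,0),(0,1,0),(0,0,1), outward faces."""
    v = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
    f = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return TriangleMesh(v, f)


@pytest.fixture
def icosphere():
    def _make(subdivisions: int = 3, radius: float = 1.0) -> TriangleMesh:
        ico = _trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
        return TriangleMesh(np.asarray(ico.vertices), np.asarray(ico.faces))

    return _make


@pytest.fixture(scope="session")
def small_dataset():
    """30 benign + 18 malignant synthetic meshes at separation 0.8."""
    return make_dataset(30, 18, separation=0.8, seed=11)


@pytest.fixture(scope="session")
def small_table(small_dataset):
    return build_feature_table(small_dataset)


@pytest.fixture(scope="session")
def small_graph(small_table):
    return build_graph(small_table, 0.7, standardize=True)
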