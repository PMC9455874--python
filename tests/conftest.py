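import numpy as np
import pytest

from phagospread.constitutive import PhysicalParams
from phagospread.geometry import CellContour, Mesh, init_spherical_cap


@pytest.fixture
def params():
    return PhysicalParams()


@pytest.fixture
def passive_params():
    return PhysicalParams(mu=200.0)


@pytest.fixture
def sphere_contour():
    """Near-complete sphere of diameter 8.5 μm, 200 free nodes, uniform."""
    return init_spherical_cap(8.5, 0.05, n_free=200, grading=1.0)


@pytest.fixture
def cap_contour():
    """Moderately spread spherical cap (contact area 3 μm²)."""
    return init_spherical_cap(8.5, 3.0, n_free=120, grading=4.0)


def make_rect_mesh(n_r, n_z=None, width=1.0, height=1.0):
    """Structured rectangle mesh on [0, width] × [0, height] with the top
    edge tagged free, right+bottom adherent and the left edge on the axis."""
    n_z = n_r if n_z is None else n_z
    xs = np.linspace(0.0, width, n_r)
    zs = np.linspace(0.0, height, n_z)
    R, Z = np.meshgrid(xs, zs, indexing="ij")
    coords = np.column_stack([R.ravel(), Z.ravel()])

    def nid(i, j):
        return i * n_z + j

    quads = np.array([[nid(i, j), nid(i + 1, j), nid(i + 1, j + 1), nid(i, j + 1)]
                      for i in range(n_r - 1) for j in range(n_z - 1)])
    top = np.array([nid(i, n_z - 1) for i in range(n_r)])
    bottom = np.array([nid(i, 0) for i in range(n_r)])
    right = np.array([nid(n_r - 1, j) for j in range(n_z)])
    left = np.array([nid(0, j) for j in range(n_z)])
    free_edges = np.column_stack([top[:-1], top[1:]])
    adherent = np.unique(np.concatenate([right, bottom]))
    h = max(width / (n_r - 1), height / (n_z - 1))
    return Mesh(coords, quads, free_edges, np.empty((0, 2), int),
                np.empty((0, 2), int), top, adherent, left,
                (n_r, n_z), h, np.full(len(quads), h)), top


@pytest.fixture
def rect_mesh_factory():
    return make_rect_mesh
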