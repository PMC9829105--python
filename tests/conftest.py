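import numpy as np
import pytest

import centroidtrack as ct
from centroidtrack.simulate import _latlong_sphere


def make_unit_cube() -> ct.TriangleMesh:
    """Closed unit cube [0,1]^3: 8 vertices, 12 triangles."""
    v = np.array([[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)],
                 dtype=float)
    f = np.array([
        [0, 1, 3], [0, 3, 2],   # x = 0
        [4, 6, 7], [4, 7, 5],   # x = 1
        [0, 4, 5], [0, 5, 1],   # y = 0
        [2, 3, 7], [2, 7, 6],   # y = 1
        [0, 2, 6], [0, 6, 4],   # z = 0
        [1, 5, 7], [1, 7, 3],   # z = 1
    ])
    return ct.TriangleMesh(v, f, name="unit_cube")


def make_sphere(radius: float = 25.0, n_rings: int = 30,
                n_lon: int = 60) -> ct.TriangleMesh:
    v, f = _latlong_sphere(n_rings, n_lon)
    return ct.TriangleMesh(v * radius, f, name="sphere")


@pytest.fixture
def cube() -> ct.TriangleMesh:
    return make_unit_cube()


@pytest.fixture
def single_triangle() -> ct.TriangleMesh:
    return ct.TriangleMesh(
        np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]),
        np.array([[0, 1, 2]]), name="tri")


@pytest.fixture(scope="session")
def roi_small() -> ct.TriangleMesh:
    """Small maxilla-like mesh shared by registration/tracking tests."""
    return ct.generate_roi_mesh("maxilla", 800, seed=7)


@pytest.fixture(scope="session")
def mandible_small() -> ct.TriangleMesh:
    return ct.generate_roi_mesh("mandible", 800, seed=7)


def midpoint_subdivide(mesh: ct.TriangleMesh) -> ct.TriangleMesh:
    """1 -> 4 midpoint subdivision preserving the surface pointwise."""
    verts = list(mesh.vertices)
    cache: dict[tuple[int, int], int] = {}

    def midpoint(i, j):
        key = (min(i, j), max(i, j))
        if key not in cache:
            cache[key] = len(verts)
            verts.append(0.5 * (mesh.vertices[i] + mesh.vertices[j]))
        return cache[key]

    faces = []
    for a, b, c in mesh.faces:
        ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
        faces.extend([[a, ab, ca], [ab, b, bc], [ca, bc, c], [ab, bc, ca]])
    return ct.TriangleMesh(np.array(verts), np.array(faces),
                           name=mesh.name + "_sub")


def random_rotation(rng) -> np.ndarray:
    from scipy.spatial.transform import Rotation
    return Rotation.random(random_state=np.random.RandomState(
        rng.integers(2 ** 31))).as_matrix()
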