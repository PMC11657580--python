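import numpy as np
import pytest
import trimesh

from shapegrade.meshes import TriangleMesh
from shapegrade.geometry import metric_operators, eigenbasis
from shapegrade.network import ShapeBundle
from shapegrade.synthetic import uv_sphere


def tetrahedron() -> TriangleMesh:
    v = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0],
                  [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
    f = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return TriangleMesh(v, f, subject_id="tetra")


def planar_grid(n: int = 6) -> TriangleMesh:
    """Open triangulated square grid in the z = 0 plane."""
    xs = np.linspace(0.0, 1.0, n)
    vv = np.array([[x, y, 0.0] for y in xs for x in xs])
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            faces.append([a, a + 1, a + n])
            faces.append([a + 1, a + n + 1, a + n])
    return TriangleMesh(vv, np.array(faces), subject_id="grid")


def icosphere(subdivisions: int = 3) -> TriangleMesh:
    m = trimesh.creation.icosphere(subdivisions=subdivisions)
    return TriangleMesh(np.asarray(m.vertices), np.asarray(m.faces),
                        subject_id=f"ico{subdivisions}")


def torus_mesh() -> TriangleMesh:
    m = trimesh.creation.torus(major_radius=1.0, minor_radius=0.3,
                               major_sections=24, minor_sections=12)
    return TriangleMesh(np.asarray(m.vertices), np.asarray(m.faces),
                        subject_id="torus")


def bumpy_sphere(amplitude: float = 0.05, n_rings: int = 12,
                 n_lon: int = 18) -> TriangleMesh:
    """Sphere with a smooth deterministic bump field; breaks the exact
    eigenvalue degeneracies of the round sphere."""
    base = uv_sphere(n_rings, n_lon, ring_z=0.5)
    v = base.vertices
    r = 1.0 + amplitude * np.sin(3.0 * v[:, 0]) * np.cos(2.0 * v[:, 2])
    return TriangleMesh(v * r[:, None], base.faces, subject_id="bumpy")


def make_bundle(mesh: TriangleMesh, k: int, shape_id=None) -> ShapeBundle:
    ops = metric_operators(mesh, 0.0)
    return ShapeBundle(shape_id or mesh.subject_id, mesh,
                       eigenbasis(ops, k), ops)


def permuted_copy(mesh: TriangleMesh, seed: int = 1):
    """Vertex-permuted copy plus the permutation (new_j = old perm[j])."""
    perm = np.random.default_rng(seed).permutation(mesh.n_vertices)
    inv = np.empty_like(perm)
    inv[perm] = np.arange(len(perm))
    return TriangleMesh(mesh.vertices[perm], inv[mesh.faces],
                        subject_id=mesh.subject_id + "_perm"), perm


@pytest.fixture(scope="session")
def grid_mesh():
    return planar_grid()


@pytest.fixture(scope="session")
def ico3():
    return icosphere(3)


@pytest.fixture(scope="session")
def bumpy():
    return bumpy_sphere()


@pytest.fixture(scope="session")
def bumpy_bundle(bumpy):
    return make_bundle(bumpy, k=24)
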