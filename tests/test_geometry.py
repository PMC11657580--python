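import numpy as np
import pytest

from shapegrade.meshes import TriangleMesh
from shapegrade.geometry import (GeometryError, vertex_normals,
                                 isophotic_edge_lengths, metric_operators,
                                 eigenbasis, omega_from_alpha)
from shapegrade.synthetic import uv_sphere

from conftest import tetrahedron, planar_grid, icosphere, torus_mesh, \
    bumpy_sphere


# ---------------------------------------------------------------------------
# Independent oracle: classic coordinate-based cotangent Laplacian.
# Cotangents come from dot/cross products of edge vectors (never from edge
# lengths), so this shares no code path with the implementation under test.

def reference_cotangent(mesh):
    v, f = mesh.vertices, mesh.faces
    V = len(v)
    W = np.zeros((V, V))
    mass = np.zeros(V)
    for (i, j, k) in f:
        for (a, b, c) in ((i, j, k), (j, k, i), (k, i, j)):
            u1 = v[b] - v[a]
            u2 = v[c] - v[a]
            cot = np.dot(u1, u2) / np.linalg.norm(np.cross(u1, u2))
            W[b, c] -= 0.5 * cot
            W[c, b] -= 0.5 * cot
            W[b, b] += 0.5 * cot
            W[c, c] += 0.5 * cot
        area = 0.5 * np.linalg.norm(np.cross(v[j] - v[i], v[k] - v[i]))
        for vert in (i, j, k):
            mass[vert] += area / 3.0
    return mass, W


FIXTURES = [tetrahedron, lambda: planar_grid(5), lambda: icosphere(2),
            torus_mesh, lambda: uv_sphere(8, 12, ring_z=0.5)]


@pytest.mark.parametrize("maker", FIXTURES)
def test_omega0_matches_independent_cotangent_scheme(maker):
    mesh = maker()
    ops = metric_operators(mesh, 0.0)
    ref_mass, ref_W = reference_cotangent(mesh)
    assert np.abs(ops.stiffness.toarray() - ref_W).max() < 1e-10
    assert np.abs(ops.lumped_mass_diagonal() - ref_mass).max() < 1e-10


def test_square_cotangent_weights_by_hand():
    # unit square split along the diagonal (0, 2): the angles opposite the
    # diagonal are right angles (cot = 0), the angles opposite the boundary
    # edges are 45 degrees (cot = 1, one incident face -> weight 1/2)
    v = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float)
    f = np.array([[0, 1, 2], [0, 2, 3]])
    W = metric_operators(TriangleMesh(v, f), 0.0).stiffness.toarray()
    expected = np.array([[1.0, -0.5, 0.0, -0.5],
                         [-0.5, 1.0, -0.5, 0.0],
                         [0.0, -0.5, 1.0, -0.5],
                         [-0.5, 0.0, -0.5, 1.0]])
    assert np.allclose(W, expected, atol=1e-12)
    assert np.allclose(W.sum(axis=1), 0.0, atol=1e-12)


# ---------------------------------------------------------------------------
# Normals

def test_sphere_normals_point_radially(ico3):
    n = vertex_normals(ico3)
    # unit icosphere: normal ~ position
    assert np.abs(np.einsum("ij,ij->i", n, ico3.vertices) - 1.0).max() < 1e-3


def test_planar_normals_exact(grid_mesh):
    n = vertex_normals(grid_mesh)
    assert np.allclose(n, [0.0, 0.0, 1.0])


def test_flipped_orientation_negates_normals(ico3):
    flipped = TriangleMesh(ico3.vertices, ico3.faces[:, [0, 2, 1]])
    assert np.allclose(vertex_normals(flipped), -vertex_normals(ico3))


# ---------------------------------------------------------------------------
# Isophotic edge lengths

def test_omega0_lengths_euclidean(bumpy):
    normals = vertex_normals(bumpy)
    e = bumpy.edges()
    lengths = isophotic_edge_lengths(bumpy, normals, 0.0, e)
    eucl = np.linalg.norm(bumpy.vertices[e[:, 0]] - bumpy.vertices[e[:, 1]],
                          axis=1)
    assert np.allclose(lengths, eucl)


def test_planar_lengths_omega_independent(grid_mesh):
    normals = vertex_normals(grid_mesh)
    e = grid_mesh.edges()
    l0 = isophotic_edge_lengths(grid_mesh, normals, 0.0, e)
    for omega in (0.5, 10.0, 1000.0):
        assert np.allclose(isophotic_edge_lengths(grid_mesh, normals,
                                                  omega, e), l0)


def test_unit_sphere_omega1_lengths_scale_sqrt2(ico3):
    # on the unit sphere I = III (the Gauss map is the identity), so
    # omega = 1 doubles the squared metric
    e = ico3.edges()
    eucl = np.linalg.norm(ico3.vertices[e[:, 0]] - ico3.vertices[e[:, 1]],
                          axis=1)
    exact_gauss = ico3.vertices / np.linalg.norm(ico3.vertices, axis=1,
                                                 keepdims=True)
    l1 = isophotic_edge_lengths(ico3, exact_gauss, 1.0, e)
    assert np.allclose(l1, np.sqrt(2.0) * eucl, rtol=1e-9)
    # discrete area-weighted normals approximate the Gauss map on average
    l1d = isophotic_edge_lengths(ico3, vertex_normals(ico3), 1.0, e)
    assert np.mean(l1d / eucl) == pytest.approx(np.sqrt(2.0), rel=5e-2)


def test_lengths_monotone_in_omega(bumpy):
    normals = vertex_normals(bumpy)
    e = bumpy.edges()
    prev = isophotic_edge_lengths(bumpy, normals, 0.0, e)
    for omega in (0.01, 0.1, 1.0, 10.0):
        cur = isophotic_edge_lengths(bumpy, normals, omega, e)
        assert np.all(cur >= prev - 1e-15)
        prev = cur


def test_negative_omega_rejected(bumpy):
    with pytest.raises(GeometryError):
        isophotic_edge_lengths(bumpy, vertex_normals(bumpy), -1.0)


# ---------------------------------------------------------------------------
# Operators

def test_icosphere_total_area_near_4pi(ico3):
    ops = metric_operators(ico3, 0.0)
    assert ops.total_area == pytest.approx(4 * np.pi, rel=1e-2)
    assert ops.lumped_mass_diagonal().sum() == pytest.approx(ops.total_area)


def test_planar_operators_omega_independent(grid_mesh):
    ops0 = metric_operators(grid_mesh, 0.0)
    ops10 = metric_operators(grid_mesh, 10.0)
    assert np.abs((ops0.stiffness - ops10.stiffness)).max() < 1e-12
    assert np.abs((ops0.mass - ops10.mass)).max() < 1e-12


def test_total_area_monotone_in_omega(bumpy):
    areas = [metric_operators(bumpy, w).total_area
             for w in (0.0, 0.05, 0.2, 1.0)]
    assert np.all(np.diff(areas) >= -1e-12)


def test_stiffness_row_sums_zero_and_psd(bumpy):
    ops = metric_operators(bumpy, 0.3)
    W = ops.stiffness.toarray()
    assert np.abs(W.sum(axis=1)).max() < 1e-10
    vals = np.linalg.eigvalsh((W + W.T) / 2)
    assert vals.min() > -1e-10
    assert ops.lumped_mass_diagonal().min() > 0


def test_degenerate_face_raises():
    v = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], dtype=float)
    f = np.array([[0, 1, 2]])
    mesh = TriangleMesh(v, f)
    with pytest.raises(GeometryError, match="normal|degenerate"):
        metric_operators(mesh, 0.0)


# ---------------------------------------------------------------------------
# Eigenbasis

def test_icosphere_spectrum_matches_analytic(ico3):
    # unit-sphere Laplace-Beltrami eigenvalues are l(l+1), multiplicity 2l+1
    ops = metric_operators(ico3, 0.0)
    basis = eigenbasis(ops, 16)
    expected = np.array([0.0] + [2.0] * 3 + [6.0] * 5 + [12.0] * 7)
    assert basis.eigenvalues[0] == pytest.approx(0.0, abs=1e-8)
    assert np.allclose(basis.eigenvalues[1:], expected[1:], rtol=0.02)


def test_basis_orthonormal_and_sorted(bumpy_bundle):
    basis, ops = bumpy_bundle.basis, bumpy_bundle.ops
    G = basis.eigenfunctions.T @ (ops.mass @ basis.eigenfunctions)
    assert np.abs(G - np.eye(basis.k)).max() < 1e-8
    assert np.all(np.diff(basis.eigenvalues) >= -1e-12)


def test_constant_first_eigenfunction(bumpy_bundle):
    basis, ops = bumpy_bundle.basis, bumpy_bundle.ops
    const = basis.eigenfunctions[:, 0]
    expected = 1.0 / np.sqrt(ops.total_area)
    assert np.allclose(np.abs(const), expected, rtol=1e-6)


def test_spectrum_scale_covariance(bumpy):
    ops = metric_operators(bumpy, 0.0)
    vals = eigenbasis(ops, 6).eigenvalues
    scaled = TriangleMesh(2.5 * bumpy.vertices, bumpy.faces)
    vals_s = eigenbasis(metric_operators(scaled, 0.0), 6).eigenvalues
    assert np.allclose(vals_s[1:], vals[1:] / 2.5 ** 2, rtol=1e-8)


@pytest.mark.parametrize("omega", [0.0, 0.2])
def test_rigid_motion_invariance(bumpy, omega):
    from scipy.spatial.transform import Rotation
    R = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
    moved = TriangleMesh(bumpy.vertices @ R.T + np.array([1.0, -2.0, 0.5]),
                         bumpy.faces)
    v1 = eigenbasis(metric_operators(bumpy, omega), 6).eigenvalues
    v2 = eigenbasis(metric_operators(moved, omega), 6).eigenvalues
    assert np.allclose(v1, v2, rtol=1e-7, atol=1e-9)


def test_eigenbasis_k_bounds(bumpy_bundle):
    with pytest.raises(GeometryError):
        eigenbasis(bumpy_bundle.ops, bumpy_bundle.ops.n_vertices)


# ---------------------------------------------------------------------------
# omega from alpha

def test_omega_from_alpha_values():
    cube = TriangleMesh(
        np.array([[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)],
                 dtype=float), np.array([[0, 1, 2]]))
    assert omega_from_alpha(cube, 0.0) == 0.0
    assert omega_from_alpha(cube, 1.0) == pytest.approx(3.0)
    # a mesh with bounding-box diagonal exactly 1
    seg = TriangleMesh(np.array([[0., 0, 0], [1 / np.sqrt(3), 1 / np.sqrt(3),
                                              1 / np.sqrt(3)],
                                 [0.5, 0.2, 0.1]]), np.array([[0, 1, 2]]))
    assert omega_from_alpha(seg, 2.0 ** -6) == pytest.approx(0.015625,
                                                             rel=1e-9)
    with pytest.raises(GeometryError):
        omega_from_alpha(cube, -0.5)


def test_operators_hdf5_round_trip(tmp_path, bumpy_bundle):
    import h5py
    from shapegrade.geometry import save_operators, load_operators
    path = tmp_path / "ops.h5"
    with h5py.File(path, "w") as h5:
        save_operators(h5.create_group("s"), bumpy_bundle.ops,
                       bumpy_bundle.basis, checksum="abc")
    with h5py.File(path, "r") as h5:
        ops, basis = load_operators(h5["s"])
    assert np.abs((ops.stiffness - bumpy_bundle.ops.stiffness)).max() == 0
    assert np.array_equal(basis.eigenfunctions,
                          bumpy_bundle.basis.eigenfunctions)
    assert basis.k == bumpy_bundle.basis.k
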