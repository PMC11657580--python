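"""SPD shape-difference descriptors and Log-Euclidean features.

Two inner products on functions of a surface ``S`` characterize its
geometry relative to a shared latent basis:

* the area-based product ``h_a(f1, f2) = integral f1 f2 dmu_omega``
  (an L2 Gram matrix); equality across a correspondence characterizes
  locally area-preserving maps, and
* the conformal product ``h_c(f1, f2) = integral <grad f1, grad f2>
  dmu_omega`` on zero-mean functions; equality characterizes conformal maps.

Evaluated on the columns of a consistent latent basis these become small
symmetric positive-(semi)definite Gram matrices -- the shape-difference
descriptors. A map that preserves both is an isometry, so at ``omega = 0``
the descriptors are blind to extrinsic (bending) differences; ``omega > 0``
injects third-fundamental-form information and makes them curvature-aware.

For learning, descriptors are linearized by the Log-Euclidean framework:
matrix logarithm, lower-triangle vectorization, unit 2-norm scaling.
Distances between descriptors are Frobenius distances of the logarithms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import MetricOperators, SpectralBasis


class DescriptorError(ValueError):
    pass


@dataclass
class ShapeDescriptor:
    """Area-based and conformal descriptors of one shape at one omega."""

    D_area: np.ndarray
    D_conf: np.ndarray
    omega: float
    feature_area: np.ndarray
    feature_conf: np.ndarray

    @property
    def m(self) -> int:
        return self.D_area.shape[0]


def _latent_realization(Y: np.ndarray, basis: SpectralBasis) -> np.ndarray:
    k, m = Y.shape
    if k > basis.k:
        raise DescriptorError(
            f"latent coefficients use {k} basis functions, basis has {basis.k}")
    return basis.eigenfunctions[:, :k] @ Y  # (V, m)


def area_descriptor(Y: np.ndarray, basis: SpectralBasis,
                    ops_omega: MetricOperators) -> np.ndarray:
    """Gram matrix of the area-based product on the latent functions.

    ``D = F^T A_omega F`` with ``F = Phi Y`` the latent functions realized
    on the mesh; symmetrized against roundoff. With ``omega = 0`` and
    mass-orthonormal ``Y`` this is the identity.
    """
    F = _latent_realization(Y, basis)
    if F.shape[0] != ops_omega.n_vertices:
        raise DescriptorError("basis and operators sized for different meshes")
    D = F.T @ (ops_omega.mass @ F)
    return (D + D.T) / 2.0


def conformal_descriptor(Y: np.ndarray, basis: SpectralBasis,
                         ops_omega: MetricOperators) -> np.ndarray:
    """Gram matrix of the conformal (Dirichlet) product on latent functions.

    Latent functions are first projected to zero mean with respect to the
    metric density (membership in the zero-mean Sobolev space); the
    projection leaves the Dirichlet energy itself untouched but keeps the
    construction faithful to the space the product is defined on.
    """
    F = _latent_realization(Y, basis)
    if F.shape[0] != ops_omega.n_vertices:
        raise DescriptorError("basis and operators sized for different meshes")
    a = ops_omega.lumped_mass_diagonal()
    F = F - (a @ F) / a.sum()
    D = F.T @ (ops_omega.stiffness @ F)
    return (D + D.T) / 2.0


def spd_project(D: np.ndarray, epsilon: float = 1e-8) -> np.ndarray:
    """Clamp the spectrum of a symmetric matrix to a positive floor.

    Eigenvalues below ``epsilon * max(1, lambda_max)`` are raised to that
    floor, making the matrix logarithm well defined. Descriptor Grams are
    positive semidefinite by construction (constants lie in the kernel of
    the Dirichlet form), so the floor realizes strict positive definiteness
    with minimal distortion.
    """
    D = np.asarray(D, dtype=np.float64)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise DescriptorError("expected a square matrix")
    asym = np.abs(D - D.T).max() if D.size else 0.0
    if asym > 1e-8 * max(1.0, np.abs(D).max()):
        raise DescriptorError(f"matrix not symmetric (max asymmetry {asym:.2e})")
    Ds = (D + D.T) / 2.0
    vals, vecs = np.linalg.eigh(Ds)
    floor = epsilon * max(1.0, float(vals.max(initial=0.0)))
    clamped = np.maximum(vals, floor)
    if np.array_equal(clamped, vals):
        return Ds
    return (vecs * clamped) @ vecs.T


def _logm_spd(D: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh((D + D.T) / 2.0)
    if vals.min(initial=np.inf) <= 0:
        raise DescriptorError(
            "matrix is not positive definite; apply spd_project first")
    return (vecs * np.log(vals)) @ vecs.T


def le_feature(D: np.ndarray) -> np.ndarray:
    """Unit-norm lower-triangle vectorization of the matrix logarithm.

    The log of an SPD matrix is symmetric, so only the lower triangle
    (including the diagonal, row-major order) is kept; the vector is scaled
    to unit 2-norm. An exactly zero logarithm (identity descriptor) is
    returned as the zero vector -- it carries no information and the
    normalization would otherwise be undefined.
    """
    L = _logm_spd(np.asarray(D, dtype=np.float64))
    tri = L[np.tril_indices_from(L)]
    nrm = np.linalg.norm(tri)
    if nrm == 0.0:
        return tri
    return tri / nrm


def le_distance(D1: np.ndarray, D2: np.ndarray) -> float:
    """Log-Euclidean distance ``|log D1 - log D2|_F`` between SPD matrices."""
    D1 = np.asarray(D1, dtype=np.float64)
    D2 = np.asarray(D2, dtype=np.float64)
    if D1.shape != D2.shape:
        raise DescriptorError("dimension mismatch")
    return float(np.linalg.norm(_logm_spd(D1) - _logm_spd(D2)))


def compute_descriptor(Y: np.ndarray, basis: SpectralBasis,
                       ops_omega: MetricOperators,
                       epsilon: float = 1e-8) -> ShapeDescriptor:
    """Both descriptors of one shape plus their Log-Euclidean features."""
    Da = spd_project(area_descriptor(Y, basis, ops_omega), epsilon)
    Dc = spd_project(conformal_descriptor(Y, basis, ops_omega), epsilon)
    return ShapeDescriptor(D_area=Da, D_conf=Dc, omega=ops_omega.omega,
                           feature_area=le_feature(Da),
                           feature_conf=le_feature(Dc))


def concat_features(parts: list[np.ndarray]) -> np.ndarray:
    """Concatenate per-descriptor unit-norm feature vectors.

    Used for multi-descriptor / multi-side configurations; each block keeps
    its own unit norm and the concatenation is not re-normalized, so every
    descriptor contributes with equal weight.
    """
    return np.concatenate(parts)


def descriptor_distance_matrix(descs: list[ShapeDescriptor],
                               kinds: tuple[str, ...] = ("area", "conf"),
                               ) -> np.ndarray:
    """Pairwise Log-Euclidean distances over a shape collection.

    When several descriptor kinds are combined, the distance is the
    Frobenius distance of the block-diagonal logarithms, i.e. the root sum
    of squares of the per-kind Log-Euclidean distances.
    """
    n = len(descs)
    logs = {kind: [_logm_spd(getattr(d, f"D_{kind}")) for d in descs]
            for kind in kinds}
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d2 = sum(float(np.linalg.norm(logs[k][i] - logs[k][j]) ** 2)
                     for k in kinds)
            D[i, j] = D[j, i] = np.sqrt(d2)
    return D
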