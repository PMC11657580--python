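"""Pairwise functional maps: initialization, refinement, conversions.

A functional map between surfaces M and N is a linear operator
``F : X_M -> X_N`` between truncated Laplace-Beltrami eigenspaces, encoded
by a small matrix ``C`` such that coefficient vectors transform as
``a_N ~= C a_M``. A pointwise correspondence ``T : N -> M`` induces the map
``f -> f o T``; conversely a functional map can be converted back to a
pointwise one by nearest neighbors in the spectral embedding. ZoomOut
alternates these two conversions while growing the basis dimension by one
per step, upsampling a coarse landmark-based initialization into a
high-resolution map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .meshes import TriangleMesh
from .geometry import MetricOperators, SpectralBasis

# Exact brute-force spectral nearest neighbors below this vertex count,
# k-d tree above (ties then fall to the tree's ordering).
_BRUTE_FORCE_LIMIT = 5000


class FmapError(ValueError):
    pass


@dataclass
class FunctionalMap:
    """Matrix encoding of a functional map ``X_M -> X_N``.

    ``C`` has shape (k_N, k_M): it maps coefficient vectors in the source
    basis to coefficient vectors in the target basis.
    """

    C: np.ndarray
    source_id: str = ""
    target_id: str = ""

    def __post_init__(self):
        self.C = np.asarray(self.C, dtype=np.float64)
        if self.C.ndim != 2:
            raise FmapError("C must be a matrix")

    @property
    def k_M(self) -> int:
        return self.C.shape[1]

    @property
    def k_N(self) -> int:
        return self.C.shape[0]


@dataclass
class VertexMap:
    """Pointwise correspondence ``T : N -> M``.

    ``assignment[j]`` is the source (M) vertex matched to target (N) vertex
    ``j``.
    """

    assignment: np.ndarray

    def __post_init__(self):
        self.assignment = np.asarray(self.assignment, dtype=np.int64)


# ---------------------------------------------------------------------------
# Rigid registration

def farthest_point_sampling(points: np.ndarray, n: int, seed: int) -> np.ndarray:
    """Indices of ``n`` farthest-point samples; deterministic given seed."""
    rng = np.random.default_rng(seed)
    V = len(points)
    n = min(n, V)
    idx = np.empty(n, dtype=np.int64)
    idx[0] = rng.integers(V)
    d = np.linalg.norm(points - points[idx[0]], axis=1)
    for i in range(1, n):
        idx[i] = int(np.argmax(d))
        d = np.minimum(d, np.linalg.norm(points - points[idx[i]], axis=1))
    return idx


def _pca_prealign(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Coarse alignment of Y onto X by principal axes.

    The four proper-rotation sign assignments of the axes are disambiguated
    by nearest-neighbor residual, which widens the basin of convergence of
    the subsequent EM/ICP refinement well beyond ~30 degrees. The identity
    transform competes as a candidate: for shapes already in a common pose
    (or with degenerate principal axes, e.g. surfaces of revolution) it
    wins and no spurious rotation is introduced.
    """
    mu_x, mu_y = X.mean(axis=0), Y.mean(axis=0)
    Ux = np.linalg.eigh(np.cov((X - mu_x).T))[1][:, ::-1]
    Uy = np.linalg.eigh(np.cov((Y - mu_y).T))[1][:, ::-1]
    tree = cKDTree(X)
    d0, _ = tree.query(Y)
    best = (float((d0 ** 2).mean()), np.eye(3), np.zeros(3))
    for sx in (1, -1):
        for sy in (1, -1):
            S = np.diag([sx, sy, sx * sy *
                         np.sign(np.linalg.det(Ux) * np.linalg.det(Uy))])
            R = Ux @ S @ Uy.T
            if np.linalg.det(R) < 0:
                R = Ux @ (S * np.array([1, 1, -1])) @ Uy.T
            t = mu_x - R @ mu_y
            d, _ = tree.query(Y @ R.T + t)
            err = float((d ** 2).mean())
            if err < best[0]:
                best = (err, R, t)
    return best[1], best[2]


def rigid_cpd(X: np.ndarray, Y: np.ndarray, max_iter: int = 40,
              tol: float = 1e-8, w: float = 0.0) -> tuple[np.ndarray, np.ndarray, float]:
    """Rigid coherent point drift: align point set ``Y`` onto ``X``.

    EM point-set registration with an isotropic Gaussian mixture centered on
    the moving points and a closed-form rigid (rotation + translation)
    M-step. Returns ``(R, t, sigma2)`` such that ``Y @ R.T + t`` matches X.
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    N, D = X.shape
    M = len(Y)
    R = np.eye(D)
    t = np.zeros(D)
    TY = Y.copy()
    sigma2 = ((X[:, None, :] - TY[None, :, :]) ** 2).sum() / (D * M * N)
    const = 0.0
    for _ in range(max_iter):
        # E-step: responsibilities P[m, n]
        d2 = cdist(TY, X, "sqeuclidean")
        P = np.exp(-d2 / (2.0 * sigma2))
        if w > 0:
            const = (2 * np.pi * sigma2) ** (D / 2) * w / (1 - w) * M / N
        denom = P.sum(axis=0) + const + 1e-300
        P /= denom
        Np = P.sum()
        if Np < 1e-12:
            break
        mu_x = (P.sum(axis=0) @ X) / Np
        mu_y = (P.sum(axis=1) @ Y) / Np
        Xh = X - mu_x
        Yh = Y - mu_y
        A = Xh.T @ P.T @ Yh
        U, _, Vt = np.linalg.svd(A)
        S = np.eye(D)
        S[-1, -1] = np.sign(np.linalg.det(U @ Vt))
        R = U @ S @ Vt
        t = mu_x - R @ mu_y
        TY = Y @ R.T + t
        trAR = np.trace(A.T @ R)
        xPx = np.einsum("n,ni,ni->", P.sum(axis=0), Xh, Xh)
        yPy = np.einsum("m,mi,mi->", P.sum(axis=1), Yh, Yh)
        new_sigma2 = max((xPx - 2 * trAR + yPy) / (Np * D), 1e-12)
        if abs(new_sigma2 - sigma2) < tol * sigma2:
            sigma2 = new_sigma2
            break
        sigma2 = new_sigma2
    return R, t, sigma2


def rigid_icp(X: np.ndarray, Y: np.ndarray, max_iter: int = 30,
              tol: float = 1e-10) -> tuple[np.ndarray, np.ndarray, float]:
    """Point-to-point iterative closest point; fallback registration."""
    R = np.eye(3)
    t = np.zeros(3)
    tree = cKDTree(X)
    prev = np.inf
    TY = Y.copy()
    for _ in range(max_iter):
        d, nn = tree.query(TY)
        err = float((d ** 2).mean())
        target = X[nn]
        mu_x = target.mean(axis=0)
        mu_y = Y.mean(axis=0)
        A = (target - mu_x).T @ (Y - mu_y)
        U, _, Vt = np.linalg.svd(A)
        S = np.eye(3)
        S[-1, -1] = np.sign(np.linalg.det(U @ Vt))
        R = U @ S @ Vt
        t = mu_x - R @ mu_y
        TY = Y @ R.T + t
        if prev - err < tol * max(prev, 1e-30):
            break
        prev = err
    return R, t, prev


def initial_landmarks(mesh_M: TriangleMesh, mesh_N: TriangleMesh,
                      n_landmarks: int, seed: int,
                      method: str = "cpd", subsample: int = 300,
                      ) -> list[tuple[int, int]]:
    """Approximate landmark correspondences between two meshes.

    Rigidly registers N onto M (PCA pre-alignment with the identity as a
    competing candidate, then coherent point drift on farthest-point
    subsamples; plain ICP as fallback), picks ``n_landmarks`` farthest-point
    samples on M and pairs each with the nearest aligned vertex of N.
    Deterministic given ``seed``.

    ``method="none"`` skips rigid alignment entirely and pairs landmarks in
    the given coordinate frame. Use it for collections acquired or
    constructed in a common frame: rigid re-alignment is ambiguous for
    shapes with (near-)symmetries -- it may lock onto an extrinsic symmetry
    instead of the collection's natural correspondence family, and no local
    criterion can tell the two apart.
    """
    if mesh_M.n_vertices == 0 or mesh_N.n_vertices == 0:
        raise FmapError("empty mesh")
    if n_landmarks > min(mesh_M.n_vertices, mesh_N.n_vertices):
        raise FmapError("more landmarks requested than vertices available")
    VM, VN = mesh_M.vertices, mesh_N.vertices
    if method == "none":
        aligned_N = VN
    elif method in ("cpd", "icp"):
        sub_M = VM[farthest_point_sampling(VM, min(subsample, len(VM)),
                                           seed)]
        sub_N = VN[farthest_point_sampling(VN, min(subsample, len(VN)),
                                           seed + 1)]
        R0, t0 = _pca_prealign(sub_M, sub_N)
        pre_N = sub_N @ R0.T + t0
        if method == "cpd":
            R, t, sigma2 = rigid_cpd(sub_M, pre_N)
            if not np.isfinite(sigma2):
                R, t, _ = rigid_icp(sub_M, pre_N)
        else:
            R, t, _ = rigid_icp(sub_M, pre_N)
        aligned_N = (VN @ R0.T + t0) @ R.T + t
    else:
        raise FmapError(f"unknown registration method {method!r}")
    lm_M = farthest_point_sampling(VM, n_landmarks, seed + 2)
    tree = cKDTree(aligned_N)
    _, lm_N = tree.query(VM[lm_M])
    return [(int(i), int(j)) for i, j in zip(lm_M, lm_N)]


# ---------------------------------------------------------------------------
# Functional-map algebra

def fmap_from_landmarks(basis_M: SpectralBasis, basis_N: SpectralBasis,
                        landmarks: list[tuple[int, int]], k0: int,
                        ridge: float = 1e-8) -> FunctionalMap:
    """Least-squares functional map from landmark correspondences.

    Solves ``C @ Phi_M[lm_M, :k0].T ~= Phi_N[lm_N, :k0].T`` in the ridge-
    regularized least-squares sense (the tiny ridge only conditions the
    normal equations).
    """
    if k0 > min(basis_M.k, basis_N.k):
        raise FmapError(f"k0={k0} exceeds basis size")
    if len(landmarks) < k0:
        raise FmapError(
            f"{len(landmarks)} landmarks cannot determine a {k0}x{k0} map; "
            "provide at least k0 landmarks")
    lm = np.asarray(landmarks, dtype=np.int64)
    A = basis_M.eigenfunctions[lm[:, 0], :k0].T  # (k0, L)
    B = basis_N.eigenfunctions[lm[:, 1], :k0].T  # (k0, L)
    G = A @ A.T
    G[np.diag_indices_from(G)] += ridge
    try:
        C = np.linalg.solve(G, A @ B.T).T
    except np.linalg.LinAlgError as exc:
        raise FmapError(
            "rank-deficient landmark system; add more landmarks") from exc
    return FunctionalMap(C)


def _spectral_nn(source_emb: np.ndarray, target_emb: np.ndarray) -> np.ndarray:
    """For each target row, index of the nearest source row.

    Brute force (exact, smallest-index ties) for small meshes; k-d tree
    beyond ``_BRUTE_FORCE_LIMIT`` rows.
    """
    if len(source_emb) <= _BRUTE_FORCE_LIMIT:
        d2 = cdist(target_emb, source_emb, "sqeuclidean")
        return np.argmin(d2, axis=1)
    tree = cKDTree(source_emb)
    _, nn = tree.query(target_emb)
    return nn


def pointwise_from_fmap(fmap: FunctionalMap, basis_M: SpectralBasis,
                        basis_N: SpectralBasis) -> VertexMap:
    """Convert a functional map to a pointwise map by spectral NN search.

    Target vertex ``j`` of N is matched to the source vertex ``i`` of M
    minimizing ``|C Phi_M[i] - Phi_N[j]|``.
    """
    kN, kM = fmap.C.shape
    if kM > basis_M.k or kN > basis_N.k:
        raise FmapError("map dimensions exceed available basis columns")
    src = basis_M.eigenfunctions[:, :kM] @ fmap.C.T  # (V_M, kN)
    tgt = basis_N.eigenfunctions[:, :kN]
    return VertexMap(_spectral_nn(src, tgt))


def fmap_from_pointwise(vmap: VertexMap, basis_M: SpectralBasis,
                        basis_N: SpectralBasis, mass_N: MetricOperators,
                        k: int) -> FunctionalMap:
    """Functional map induced by a pointwise map ``T : N -> M``.

    ``C = Phi_N^T A_N Pi Phi_M`` with ``Pi`` the 0/1 pullback matrix of the
    vertex map -- the mass-orthogonal projection of pulled-back basis
    functions onto the target basis.
    """
    if k > min(basis_M.k, basis_N.k):
        raise FmapError(f"k={k} exceeds basis size")
    pulled = basis_M.eigenfunctions[vmap.assignment, :k]  # (V_N, k)
    return FunctionalMap(basis_N.eigenfunctions[:, :k].T
                         @ (mass_N.mass @ pulled))


def zoomout_refine(fmap0: FunctionalMap, basis_M: SpectralBasis,
                   basis_N: SpectralBasis, mass_N: MetricOperators,
                   steps: int) -> FunctionalMap:
    """Spectral upsampling: alternate pointwise/functional conversion,
    growing the basis dimension by one per step."""
    k0 = fmap0.C.shape[0]
    if fmap0.C.shape[0] != fmap0.C.shape[1]:
        raise FmapError("ZoomOut expects a square initialization")
    if k0 + steps > min(basis_M.k, basis_N.k):
        raise FmapError(
            f"k0 + steps = {k0 + steps} exceeds basis size "
            f"{min(basis_M.k, basis_N.k)}")
    fmap = fmap0
    for step in range(steps):
        vmap = pointwise_from_fmap(fmap, basis_M, basis_N)
        fmap = fmap_from_pointwise(vmap, basis_M, basis_N, mass_N,
                                   k0 + step + 1)
    fmap.source_id = fmap0.source_id
    fmap.target_id = fmap0.target_id
    return fmap


def cycle_consistency(fmap_MN: FunctionalMap, fmap_NM: FunctionalMap) -> float:
    """2-cycle consistency ``|C_NM C_MN - I|_F`` of a map pair."""
    if fmap_NM.C.shape[1] != fmap_MN.C.shape[0]:
        raise FmapError("incompatible map dimensions")
    prod = fmap_NM.C @ fmap_MN.C
    return float(np.linalg.norm(prod - np.eye(prod.shape[0])))


def map_distortion(vmap: VertexMap, mesh_M: TriangleMesh,
                   mesh_N: TriangleMesh) -> float:
    """Mean relative edge-length distortion of a pointwise map (diagnostic).

    For every edge of N, compares its length with the length of the image
    segment on M; useful to judge whether a refined map realizes a small
    deformation.
    """
    e = mesh_N.edges()
    ln = np.linalg.norm(mesh_N.vertices[e[:, 0]] - mesh_N.vertices[e[:, 1]],
                        axis=1)
    img = vmap.assignment
    lm = np.linalg.norm(mesh_M.vertices[img[e[:, 0]]]
                        - mesh_M.vertices[img[e[:, 1]]], axis=1)
    ok = ln > 1e-300
    return float(np.mean(np.abs(lm[ok] - ln[ok]) / ln[ok]))
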