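"""Functional-map networks and the consistent latent basis (CLB).

A shape collection is organized as a graph whose nodes are shapes and whose
edges carry functional maps. Unreliable maps are pruned by keeping, for each
shape, its k most 2-cycle-consistent neighbors, with k the smallest value
that leaves the graph connected. On the pruned network a consistent latent
basis -- one coefficient matrix ``Y_S`` per shape whose columns represent
the same latent functions everywhere -- is computed by minimizing

    sum over edges (M, N) of  |C_MN Y_M - Y_N|_F^2

under the stacked orthonormality constraint ``sum_S Y_S^T Y_S = n I``,
i.e. as the smallest eigenvectors of the network's quadratic form.
Consistent ZoomOut alternates this latent-basis computation with a ZoomOut
refinement of each edge map through the latent embedding while growing the
spectral dimension by one and the latent dimension by a fractional schedule
per step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .geometry import MetricOperators, SpectralBasis, _fix_signs
from .fmaps import (FunctionalMap, FmapError, initial_landmarks,
                    fmap_from_landmarks, fmap_from_pointwise,
                    pointwise_from_fmap, zoomout_refine, cycle_consistency,
                    VertexMap, _spectral_nn)
from .meshes import TriangleMesh


class NetworkError(ValueError):
    pass


@dataclass
class ShapeBundle:
    """A shape with its precomputed operators and eigenbasis."""

    shape_id: str
    mesh: TriangleMesh
    basis: SpectralBasis
    ops: MetricOperators


@dataclass
class MapNetwork:
    shape_ids: list
    maps: dict            # (src_id, tgt_id) -> FunctionalMap
    consistency: np.ndarray
    edges: list = field(default_factory=list)  # ordered pairs of ids
    k_used: int | None = None

    @property
    def n(self) -> int:
        return len(self.shape_ids)

    def index(self, shape_id) -> int:
        return self.shape_ids.index(shape_id)


@dataclass
class ConsistentLatentBasis:
    """Per-shape coefficient matrices of a shared latent basis.

    ``Y[shape_id]`` has shape (k_S, m): its columns express the m latent
    functions in that shape's Laplace-Beltrami eigenbasis.
    """

    Y: dict
    m: int
    residual: float
    schedule_log: list = field(default_factory=list)
    # residual of the latent basis computed at the same dimensions from the
    # unrefined maps; the refined residual must not exceed it
    init_residual: float | None = None


def all_pairs_fmaps(shapes: list, n_landmarks: int = 130, k0: int = 30,
                    zoomout_steps: int = 12, seed: int = 0,
                    registration: str = "cpd") -> MapNetwork:
    """ZoomOut-refined functional map for every ordered shape pair.

    The symmetric consistency matrix holds the 2-cycle consistency score of
    each unordered pair. Pairs whose map computation fails are excluded with
    a warning; the network may still be connectable.
    """
    if len(shapes) < 2:
        raise NetworkError("need at least 2 shapes")
    n = len(shapes)
    ids = [s.shape_id for s in shapes]
    maps: dict = {}
    consistency = np.full((n, n), np.inf)
    np.fill_diagonal(consistency, 0.0)
    for i in range(n):
        for j in range(i + 1, n):
            pair_seed = seed + 7919 * i + j
            try:
                for a, b in ((i, j), (j, i)):
                    M, N = shapes[a], shapes[b]
                    lm = initial_landmarks(M.mesh, N.mesh, n_landmarks,
                                           seed=pair_seed, method=registration)
                    f0 = fmap_from_landmarks(M.basis, N.basis, lm, k0)
                    f0.source_id, f0.target_id = M.shape_id, N.shape_id
                    maps[(M.shape_id, N.shape_id)] = zoomout_refine(
                        f0, M.basis, N.basis, N.ops, zoomout_steps)
                score = cycle_consistency(maps[(ids[i], ids[j])],
                                          maps[(ids[j], ids[i])])
                consistency[i, j] = consistency[j, i] = score
            except (FmapError, np.linalg.LinAlgError) as exc:
                maps.pop((ids[i], ids[j]), None)
                maps.pop((ids[j], ids[i]), None)
                warnings.warn(f"map computation failed for pair "
                              f"({ids[i]}, {ids[j]}): {exc}", stacklevel=2)
    return MapNetwork(shape_ids=ids, maps=maps, consistency=consistency)


def consistency_knn_graph(consistency: np.ndarray) -> tuple[list, int]:
    """Symmetrized k-NN edge set at the smallest k that connects the graph.

    Neighbors are ranked by ascending 2-cycle-consistency score (lower is
    better). Returns (ordered index-pair edges, k_used).
    """
    Cn = np.asarray(consistency, dtype=float)
    n = Cn.shape[0]
    if n < 2 or Cn.shape[0] != Cn.shape[1]:
        raise NetworkError("consistency matrix must be square with n >= 2")
    if not np.isfinite(Cn[~np.eye(n, dtype=bool)]).any():
        raise NetworkError("no usable maps: all consistency scores infinite")
    order = np.argsort(Cn + np.where(np.eye(n, dtype=bool), np.inf, 0.0),
                       axis=1, kind="stable")
    for k in range(1, n):
        adj = np.zeros((n, n), dtype=bool)
        for i in range(n):
            nbrs = [j for j in order[i] if np.isfinite(Cn[i, j])][:k]
            adj[i, nbrs] = True
        adj |= adj.T  # symmetrize by union
        ncomp, _ = connected_components(sp.csr_matrix(adj), directed=False)
        if ncomp == 1:
            edges = [(i, j) for i in range(n) for j in range(n)
                     if adj[i, j] and i != j]
            return edges, k
    raise NetworkError("graph cannot be connected from the available maps")


def prune_network(network: MapNetwork) -> MapNetwork:
    """Restrict a full network to its consistency-k-NN edge set."""
    edges_idx, k_used = consistency_knn_graph(network.consistency)
    ids = network.shape_ids
    edges = [(ids[i], ids[j]) for i, j in edges_idx]
    maps = {e: network.maps[e] for e in edges if e in network.maps}
    return MapNetwork(shape_ids=ids, maps=maps,
                      consistency=network.consistency,
                      edges=edges, k_used=k_used)


def _stacked_quadratic_form(network: MapNetwork, dim: int) -> np.ndarray:
    """Block matrix H with  sum_edges |C Y_M - Y_N|^2 = tr(Y^T H Y)."""
    n = network.n
    H = np.zeros((n * dim, n * dim))
    eye = np.eye(dim)
    for (src, tgt) in network.edges:
        if (src, tgt) not in network.maps:
            continue
        i, j = network.index(src), network.index(tgt)
        C = network.maps[(src, tgt)].C[:dim, :dim]
        si, sj = slice(i * dim, (i + 1) * dim), slice(j * dim, (j + 1) * dim)
        H[si, si] += C.T @ C
        H[si, sj] += -C.T
        H[sj, si] += -C
        H[sj, sj] += eye
    return (H + H.T) / 2.0


def clb_residual(network: MapNetwork, Y: dict, dim: int | None = None) -> float:
    """Recompute the CLB objective by direct summation over edges."""
    total = 0.0
    for (src, tgt) in network.edges:
        if (src, tgt) not in network.maps:
            continue
        d = dim or Y[src].shape[0]
        C = network.maps[(src, tgt)].C[:d, :d]
        total += float(np.linalg.norm(C @ Y[src][:d] - Y[tgt][:d]) ** 2)
    return total


def canonical_latent_basis(network: MapNetwork, m: int,
                           dim: int | None = None) -> ConsistentLatentBasis:
    """Consistent latent basis as smallest eigenvectors of the network form.

    Maps are truncated to their leading ``dim x dim`` blocks (defaults to
    the full map dimension). The stacked coefficient matrix collects the m
    eigenvectors of smallest eigenvalue, scaled so that
    ``sum_S Y_S^T Y_S = n I_m``, with deterministic sign fixing.
    """
    if not network.edges:
        raise NetworkError("network has no edges; prune or build one first")
    dims = [network.maps[e].C.shape[0] for e in network.edges
            if e in network.maps]
    full = min(dims)
    dim = full if dim is None else dim
    if dim > full:
        raise NetworkError(f"requested dim {dim} exceeds map dim {full}")
    if m > dim:
        raise NetworkError(f"latent dimension m={m} exceeds map dim {dim}")
    H = _stacked_quadratic_form(network, dim)
    try:
        vals, vecs = np.linalg.eigh(H)
    except np.linalg.LinAlgError as exc:
        raise NetworkError(f"CLB eigen-solver failed: {exc}") from exc
    U = _fix_signs(vecs[:, :m]) * np.sqrt(network.n)
    Y = {sid: U[i * dim:(i + 1) * dim] for i, sid in
         enumerate(network.shape_ids)}
    return ConsistentLatentBasis(Y=Y, m=m,
                                 residual=clb_residual(network, Y, dim))


def consistent_zoomout(network: MapNetwork, shapes: list,
                       init_dim: int = 8, steps: int = 20,
                       basis_step: int = 1, latent_step: float = 0.7,
                       ) -> ConsistentLatentBasis:
    """Network-wide spectral upsampling producing a refined CLB.

    Starting from the leading ``init_dim`` blocks of all edge maps, each
    step (a) recomputes the latent basis at the current dimensions,
    (b) refines every edge map by one ZoomOut step routed through the latent
    embedding (latent functions realized on both shapes, nearest-neighbor
    pointwise map, re-projection at the grown dimension), and (c) grows the
    spectral dimension by ``basis_step`` while a real-valued accumulator
    adds ``latent_step``; the instantiated latent size is its floor. With
    the defaults the schedule ends at spectral dimension 28 and latent
    dimension 22.
    """
    if not network.edges:
        raise NetworkError("network has no edges; prune it first")
    bundle = {s.shape_id: s for s in shapes}
    dims = [network.maps[e].C.shape[0] for e in network.edges]
    max_dim = min(min(dims), min(s.basis.k for s in shapes))
    if init_dim + steps * basis_step > max_dim:
        raise NetworkError(
            f"schedule overflows available dimension: need "
            f"{init_dim + steps * basis_step}, have {max_dim}")
    maps = {e: FunctionalMap(network.maps[e].C[:init_dim, :init_dim],
                             *e) for e in network.edges}
    work = MapNetwork(network.shape_ids, maps, network.consistency,
                      list(network.edges), network.k_used)
    dim = init_dim
    latent_acc = float(init_dim)
    log = []
    for _ in range(steps):
        m = int(np.floor(latent_acc + 1e-9))
        clb = canonical_latent_basis(work, m=m, dim=dim)
        log.append((dim, m))
        new_dim = dim + basis_step
        for (src, tgt) in work.edges:
            M, N = bundle[src], bundle[tgt]
            emb_M = M.basis.eigenfunctions[:, :dim] @ clb.Y[src]
            emb_N = N.basis.eigenfunctions[:, :dim] @ clb.Y[tgt]
            vmap = VertexMap(_spectral_nn(emb_M, emb_N))  # T : N -> M
            work.maps[(src, tgt)] = fmap_from_pointwise(
                vmap, M.basis, N.basis, N.ops, new_dim)
            work.maps[(src, tgt)].source_id = src
            work.maps[(src, tgt)].target_id = tgt
        dim = new_dim
        latent_acc += latent_step
    m_final = int(np.floor(latent_acc + 1e-9))
    clb = canonical_latent_basis(work, m=m_final, dim=dim)
    log.append((dim, m_final))
    clb.schedule_log = log
    # baseline: latent basis at the same final dimensions from the
    # unrefined maps -- refinement must not be worse
    clb.init_residual = canonical_latent_basis(network, m=m_final,
                                               dim=dim).residual
    return clb


# ---------------------------------------------------------------------------
# HDF5 serialization

def save_network(h5group, network: MapNetwork,
                 clb: ConsistentLatentBasis | None = None) -> None:
    h5group.create_dataset("consistency", data=network.consistency)
    ids = [str(s) for s in network.shape_ids]
    h5group.attrs["shape_ids"] = ids
    if network.k_used is not None:
        h5group.attrs["k_used"] = network.k_used
    if network.edges:
        h5group.create_dataset(
            "edges", data=np.array([[network.index(a), network.index(b)]
                                    for a, b in network.edges]))
    g = h5group.create_group("maps")
    for (src, tgt), fmap in network.maps.items():
        g.create_dataset(f"{src}__{tgt}", data=fmap.C)
    if clb is not None:
        gc = h5group.create_group("clb")
        for sid, Y in clb.Y.items():
            gc.create_dataset(str(sid), data=Y)
        gc.attrs["m"] = clb.m
        gc.attrs["residual"] = clb.residual
        if clb.schedule_log:
            h5group.create_dataset("schedule_log",
                                   data=np.array(clb.schedule_log))
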