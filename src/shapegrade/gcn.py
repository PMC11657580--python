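"""Population-graph construction and transductive Chebyshev-GCN grading.

Subjects become nodes of a population graph whose adjacency combines a
shape-similarity kernel with a phenotype gate:

    W_ij = Sim(S_i, S_j) * gate(i, j)

``Sim`` is a radial basis function of the Log-Euclidean descriptor
distances, with bandwidth sigma set to the median of all pairwise
distances. The gate is 1 iff sex and ApoE genotype both coincide and one
subject is among the k nearest neighbors of the other (k = 30 by default).

Classification is semi-supervised node classification with a feed-forward
graph convolutional network using K-th order Chebyshev polynomial filters of
the rescaled normalized Laplacian. The network is a compact, self-contained
dense implementation (forward, analytic backward pass, Adam) -- adequate for
population graphs of a few hundred nodes and fully deterministic given a
seed. Evaluation uses repeated stratified Monte Carlo train/test splits with
full retraining per draw.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class GraphError(ValueError):
    pass


@dataclass
class PopulationGraph:
    W: np.ndarray
    Sim: np.ndarray
    delta_mask: np.ndarray
    sigma: float
    distances: np.ndarray
    features: np.ndarray
    labels: np.ndarray           # integer class per subject
    phenotypes: pd.DataFrame
    class_names: list = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.labels)


@dataclass
class GCNConfig:
    """Architecture and training hyper-parameters.

    Defaults: three Chebyshev convolution layers of order K=2 with hidden
    widths (64, 64), ReLU and dropout after each hidden layer, Adam with
    learning rate 1e-2 and weight decay 5e-4, 200 epochs.
    """

    cheb_order: int = 2
    hidden_dims: tuple = (64, 64)
    epochs: int = 200
    learning_rate: float = 1e-2
    weight_decay: float = 5e-4
    dropout: float = 0.5
    seed: int = 0
    lambda_max: str = "exact"     # exact top eigenvalue or fixed "two"

    def __post_init__(self):
        if self.cheb_order < 1:
            raise GraphError("cheb_order must be >= 1")
        if len(self.hidden_dims) < 1:
            raise GraphError("need at least one hidden layer")


@dataclass
class EvalResult:
    accuracy: float
    precision: float
    recall: float
    specificity: float
    per_draw: list = field(default_factory=list)
    summary: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Graph construction

def similarity_matrix(distances: np.ndarray) -> tuple[np.ndarray, float]:
    """RBF similarity ``exp(-0.5 d^2 / sigma^2)`` with median bandwidth.

    sigma is the median over the n(n-1)/2 off-diagonal pairwise distances.
    """
    D = np.asarray(distances, dtype=float)
    n = D.shape[0]
    if n < 2 or D.shape[0] != D.shape[1]:
        raise GraphError("distance matrix must be square with n >= 2")
    iu = np.triu_indices(n, k=1)
    sigma = float(np.median(D[iu]))
    if sigma == 0.0:
        raise GraphError("all pairwise distances are zero; sigma undefined")
    return np.exp(-0.5 * D ** 2 / sigma ** 2), sigma


def phenotype_gate(phenotypes: pd.DataFrame, distances: np.ndarray,
                   knn: int = 30) -> np.ndarray:
    """Binary gate: matching sex AND ApoE AND mutual-or-one-way k-NN.

    ``gate[i, j] = 1`` iff sex and ApoE genotype of i and j coincide and at
    least one of the two is among the knn closest neighbors of the other in
    descriptor distance. Symmetric with zero diagonal.
    """
    n = len(phenotypes)
    if distances.shape != (n, n):
        raise GraphError("phenotype table and distance matrix disagree on n")
    if knn >= n:
        raise GraphError(f"knn={knn} must be smaller than n={n}")
    for col in ("sex", "apoe"):
        if col not in phenotypes.columns:
            raise GraphError(f"phenotype table lacks column {col!r}")
        missing = phenotypes[col].isna()
        if missing.any():
            subj = phenotypes.index[missing].tolist() if \
                "subject_id" not in phenotypes.columns else \
                phenotypes.loc[missing, "subject_id"].tolist()
            raise GraphError(f"missing {col} for subjects {subj}")
    sex = phenotypes["sex"].to_numpy()
    apoe = phenotypes["apoe"].to_numpy()
    match = (sex[:, None] == sex[None, :]) & (apoe[:, None] == apoe[None, :])
    D = np.asarray(distances, dtype=float).copy()
    np.fill_diagonal(D, np.inf)
    order = np.argsort(D, axis=1, kind="stable")[:, :knn]
    in_knn = np.zeros((n, n), dtype=bool)
    rows = np.repeat(np.arange(n), knn)
    in_knn[rows, order.ravel()] = True
    gate = match & (in_knn | in_knn.T)
    np.fill_diagonal(gate, False)
    return gate.astype(float)


def population_adjacency(Sim: np.ndarray, gate: np.ndarray) -> np.ndarray:
    """Elementwise product of similarity and gate, diagonal zeroed."""
    if Sim.shape != gate.shape:
        raise GraphError("Sim and gate dimensions differ")
    W = Sim * gate
    np.fill_diagonal(W, 0.0)
    isolated = int(np.sum(W.sum(axis=1) == 0))
    if isolated:
        warnings.warn(f"{isolated} isolated nodes in the population graph",
                      stacklevel=2)
    return W


def scaled_laplacian(W: np.ndarray, lambda_max: str = "exact") -> np.ndarray:
    """Rescaled normalized Laplacian ``2 L / lambda_max - I``.

    ``L = I - D^{-1/2} W D^{-1/2}`` (zero-degree rows use 0 for the inverse
    root). By default lambda_max is the exact top eigenvalue of L (dense
    symmetric solve; population graphs are small), which keeps the spectrum
    of the result inside [-1, 1]; the common shortcut lambda_max := 2 is
    available as ``"two"``. For an empty graph L = I and the convention
    lambda_max := 1 returns the identity.
    """
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    deg = W.sum(axis=1)
    dinv = np.where(deg > 0, 1.0 / np.sqrt(np.where(deg > 0, deg, 1.0)), 0.0)
    L = np.eye(n) - (dinv[:, None] * W) * dinv[None, :]
    L = (L + L.T) / 2.0
    if lambda_max == "two":
        lam = 2.0
    elif np.allclose(W, 0.0):
        lam = 1.0
    else:
        lam = float(np.linalg.eigvalsh(L)[-1])
        lam = min(max(lam, 1e-12), 2.0)
    return 2.0 * L / lam - np.eye(n)


def cheb_polynomials(Lt: np.ndarray, K: int) -> list[np.ndarray]:
    """T_0..T_K of the rescaled Laplacian via the three-term recurrence."""
    n = Lt.shape[0]
    T = [np.eye(n)]
    if K >= 1:
        T.append(Lt.copy())
    for _ in range(2, K + 1):
        T.append(2.0 * Lt @ T[-1] - T[-2])
    return T


def cheb_conv(Lt: np.ndarray, X: np.ndarray, theta: np.ndarray,
              K: int | None = None) -> np.ndarray:
    """Chebyshev graph convolution ``sum_k T_k(Lt) X Theta_k``.

    ``theta`` has shape (K+1, f_in, f_out).
    """
    theta = np.asarray(theta, dtype=float)
    if K is None:
        K = theta.shape[0] - 1
    if theta.shape[0] != K + 1 or theta.shape[1] != X.shape[1]:
        raise GraphError("theta shape inconsistent with K and feature dim")
    T = cheb_polynomials(Lt, K)
    out = np.zeros((X.shape[0], theta.shape[2]))
    for k in range(K + 1):
        out += (T[k] @ X) @ theta[k]
    return out


# ---------------------------------------------------------------------------
# Self-contained dense Chebyshev GCN

def _init_params(dims: list[int], K: int, rng: np.random.Generator) -> dict:
    params = {}
    for layer, (fi, fo) in enumerate(zip(dims[:-1], dims[1:])):
        scale = np.sqrt(2.0 / ((K + 1) * fi + fo))  # Glorot-style
        params[f"theta{layer}"] = rng.normal(0.0, scale, size=(K + 1, fi, fo))
        params[f"bias{layer}"] = np.zeros(fo)
    return params


def _forward(T: list[np.ndarray], X: np.ndarray, params: dict,
             n_layers: int, dropout: float,
             rng: np.random.Generator | None) -> tuple[np.ndarray, list]:
    """Forward pass; returns logits and a cache for the backward pass."""
    cache = []
    H = X
    for layer in range(n_layers):
        theta = params[f"theta{layer}"]
        TX = [Tk @ H for Tk in T]
        Z = sum(tx @ theta[k] for k, tx in enumerate(TX)) \
            + params[f"bias{layer}"]
        if layer < n_layers - 1:
            A = np.maximum(Z, 0.0)
            if rng is not None and dropout > 0:
                mask = (rng.random(A.shape) >= dropout) / (1.0 - dropout)
                A = A * mask
            else:
                mask = None
            cache.append((TX, Z, mask))
            H = A
        else:
            cache.append((TX, Z, None))
            H = Z
    return H, cache


def _softmax(Z: np.ndarray) -> np.ndarray:
    Z = Z - Z.max(axis=1, keepdims=True)
    e = np.exp(Z)
    return e / e.sum(axis=1, keepdims=True)


def _backward(T: list[np.ndarray], X: np.ndarray, params: dict, cache: list,
              dZ_last: np.ndarray, n_layers: int) -> dict:
    grads = {}
    dH = dZ_last
    for layer in range(n_layers - 1, -1, -1):
        TX, Z, mask = cache[layer]
        if layer < n_layers - 1:
            if mask is not None:
                dH = dH * mask
            dH = dH * (Z > 0)
        dZ = dH
        theta = params[f"theta{layer}"]
        K1 = theta.shape[0]
        grads[f"theta{layer}"] = np.stack(
            [TX[k].T @ dZ for k in range(K1)])
        grads[f"bias{layer}"] = dZ.sum(axis=0)
        if layer > 0:
            dHprev = np.zeros_like(TX[0])
            for k in range(K1):
                dHprev += T[k].T @ (dZ @ theta[k].T)
            dH = dHprev
    return grads


def train_transductive(graph: PopulationGraph, config: GCNConfig,
                       train_idx: np.ndarray,
                       ) -> tuple[dict, np.ndarray]:
    """Train the GCN on the training nodes; return params and all-node
    class probabilities (transductive prediction).

    Cross-entropy is averaged over training nodes only, but gradients flow
    through the whole graph, so unlabeled nodes shape the learned
    representation. Deterministic given ``config.seed``.
    """
    labels = graph.labels
    classes = np.unique(labels)
    train_idx = np.asarray(train_idx, dtype=np.int64)
    present = np.unique(labels[train_idx])
    if len(present) < len(classes):
        raise GraphError("a class is missing from the training split")
    n_classes = len(classes)
    X = graph.features
    Lt = scaled_laplacian(graph.W, config.lambda_max)
    T = cheb_polynomials(Lt, config.cheb_order)
    dims = [X.shape[1], *config.hidden_dims, n_classes]
    n_layers = len(dims) - 1
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    params = _init_params(dims, config.cheb_order, rng)
    onehot = np.zeros((graph.n, n_classes))
    onehot[np.arange(graph.n), labels] = 1.0
    m_adam = {k: np.zeros_like(v) for k, v in params.items()}
    v_adam = {k: np.zeros_like(v) for k, v in params.items()}
    b1, b2, eps = 0.9, 0.999, 1e-8
    ntr = len(train_idx)
    for epoch in range(1, config.epochs + 1):
        logits, cache = _forward(T, X, params, n_layers, config.dropout, rng)
        probs = _softmax(logits)
        dZ = np.zeros_like(probs)
        dZ[train_idx] = (probs[train_idx] - onehot[train_idx]) / ntr
        grads = _backward(T, X, params, cache, dZ, n_layers)
        for k in params:
            g = grads[k]
            if k.startswith("theta"):
                g = g + config.weight_decay * params[k]
            m_adam[k] = b1 * m_adam[k] + (1 - b1) * g
            v_adam[k] = b2 * v_adam[k] + (1 - b2) * g * g
            mhat = m_adam[k] / (1 - b1 ** epoch)
            vhat = v_adam[k] / (1 - b2 ** epoch)
            params[k] -= config.learning_rate * mhat / (np.sqrt(vhat) + eps)
    logits, _ = _forward(T, X, params, n_layers, 0.0, None)
    return params, _softmax(logits)


# ---------------------------------------------------------------------------
# Evaluation

def evaluate_split(probabilities: np.ndarray, labels: np.ndarray,
                   test_idx: np.ndarray, positive_class: int = 1,
                   ) -> EvalResult:
    """Accuracy, precision, recall/sensitivity and specificity on one split.

    Ratios with zero denominator are reported as NaN with a warning.
    """
    test_idx = np.asarray(test_idx, dtype=np.int64)
    if len(test_idx) == 0:
        raise GraphError("empty test set")
    pred = probabilities[test_idx].argmax(axis=1)
    truth = labels[test_idx]
    tp = int(np.sum((pred == positive_class) & (truth == positive_class)))
    fp = int(np.sum((pred == positive_class) & (truth != positive_class)))
    fn = int(np.sum((pred != positive_class) & (truth == positive_class)))
    tn = int(np.sum((pred != positive_class) & (truth != positive_class)))

    def _ratio(num, den, name):
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator)",
                          stacklevel=3)
            return float("nan")
        return num / den

    return EvalResult(
        accuracy=(tp + tn) / len(test_idx),
        precision=_ratio(tp, tp + fp, "precision"),
        recall=_ratio(tp, tp + fn, "recall"),
        specificity=_ratio(tn, tn + fp, "specificity"),
        per_draw=[{"tp": tp, "fp": fp, "fn": fn, "tn": tn}],
    )


def stratified_split(labels: np.ndarray, train_fraction: float,
                     rng: np.random.Generator,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """One stratified train/test split.

    Per-class training counts are floor(fraction * class size); leftover
    slots up to round(fraction * n) are assigned by largest fractional
    part (ties by class order), which keeps class proportions within one
    subject of the global ones.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    raw = train_fraction * counts
    take = np.floor(raw).astype(int)
    if np.any(take == 0) or np.any(counts - take == 0):
        raise GraphError("a class is too small to stratify at this fraction")
    remainder = int(round(train_fraction * len(labels))) - take.sum()
    if remainder > 0:
        order = np.argsort(-(raw - take), kind="stable")
        for c in order[:remainder]:
            if take[c] < counts[c] - 1:
                take[c] += 1
    train, test = [], []
    for cls, ntr in zip(classes, take):
        idx = np.flatnonzero(labels == cls)
        perm = rng.permutation(len(idx))
        train.append(idx[perm[:ntr]])
        test.append(idx[perm[ntr:]])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


def monte_carlo_cv(graph: PopulationGraph, config: GCNConfig,
                   n_draws: int = 100, train_fraction: float = 0.7,
                   seed: int = 0, positive_class: int = 1) -> EvalResult:
    """Stratified Monte Carlo cross-validation with full retraining.

    Draws ``n_draws`` independent stratified train/test splits, retrains the
    GCN per draw, and summarizes each metric as mean and standard deviation
    over draws. Reproducible given ``seed``.
    """
    if not 0 < train_fraction < 1:
        raise GraphError("train_fraction must be in (0, 1)")
    ss = np.random.SeedSequence(seed)
    draws = []
    for draw, child in enumerate(ss.spawn(n_draws)):
        rng = np.random.default_rng(child)
        train_idx, test_idx = stratified_split(graph.labels, train_fraction,
                                               rng)
        cfg = GCNConfig(**{**config.__dict__,
                           "seed": int(child.generate_state(1)[0] % (2**31))})
        _, probs = train_transductive(graph, cfg, train_idx)
        res = evaluate_split(probs, graph.labels, test_idx, positive_class)
        draws.append({"draw": draw, "accuracy": res.accuracy,
                      "precision": res.precision, "recall": res.recall,
                      "specificity": res.specificity})
    summary = {}
    for metric in ("accuracy", "precision", "recall", "specificity"):
        vals = np.array([d[metric] for d in draws], dtype=float)
        ok = np.isfinite(vals)
        summary[metric] = {"mean": float(np.mean(vals[ok])) if ok.any() else float("nan"),
                           "std": float(np.std(vals[ok], ddof=1)) if ok.sum() > 1 else 0.0,
                           "n_defined": int(ok.sum())}
    return EvalResult(accuracy=summary["accuracy"]["mean"],
                      precision=summary["precision"]["mean"],
                      recall=summary["recall"]["mean"],
                      specificity=summary["specificity"]["mean"],
                      per_draw=draws, summary=summary)


def build_population_graph(distances: np.ndarray, features: np.ndarray,
                           labels: np.ndarray, phenotypes: pd.DataFrame,
                           knn: int = 30,
                           class_names: list | None = None) -> PopulationGraph:
    """Assemble the population graph from descriptor distances, features and
    phenotypes. ``knn`` is clipped to n - 1 on small cohorts."""
    n = len(labels)
    knn_eff = min(knn, n - 1)
    Sim, sigma = similarity_matrix(distances)
    gate = phenotype_gate(phenotypes, distances, knn_eff)
    W = population_adjacency(Sim, gate)
    return PopulationGraph(W=W, Sim=Sim, delta_mask=gate, sigma=sigma,
                           distances=np.asarray(distances, float),
                           features=np.asarray(features, float),
                           labels=np.asarray(labels, np.int64),
                           phenotypes=phenotypes,
                           class_names=class_names or [])
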