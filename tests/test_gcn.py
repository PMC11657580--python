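import numpy as np
import pandas as pd
import pytest

from shapegrade.gcn import (GraphError, GCNConfig, PopulationGraph,
                            similarity_matrix, phenotype_gate,
                            population_adjacency, scaled_laplacian,
                            cheb_conv, cheb_polynomials, train_transductive,
                            evaluate_split, stratified_split, monte_carlo_cv,
                            build_population_graph)


def _pheno(n, rng, sexes=None, apoes=None):
    return pd.DataFrame({
        "sex": sexes if sexes is not None else rng.choice(["F", "M"], n),
        "apoe": apoes if apoes is not None else rng.choice(
            ["E2", "E3", "E4"], n),
    })


def _blob_graph(n=40, sep=4.0, seed=0, knn=10):
    """Two Gaussian blobs with fully permissive phenotype gate."""
    rng = np.random.default_rng(seed)
    labels = np.array([0] * (n // 2) + [1] * (n - n // 2))
    X = rng.normal(size=(n, 3)) + sep * labels[:, None]
    D = np.linalg.norm(X[:, None] - X[None, :], axis=2)
    pheno = _pheno(n, rng, sexes=["F"] * n, apoes=["E3"] * n)
    return build_population_graph(D, X, labels, pheno, knn=knn)


# ---------------------------------------------------------------------------
# Similarity and gate

def test_similarity_median_bandwidth():
    D = np.array([[0.0, 1.0, 2.0],
                  [1.0, 0.0, 3.0],
                  [2.0, 3.0, 0.0]])
    Sim, sigma = similarity_matrix(D)
    assert sigma == 2.0
    assert Sim[0, 0] == 1.0
    assert Sim[0, 2] == pytest.approx(np.exp(-0.5))  # d = sigma
    assert Sim[0, 1] == pytest.approx(np.exp(-0.5 * 1.0 / 4.0))


def test_similarity_rejects_zero_distances():
    with pytest.raises(GraphError):
        similarity_matrix(np.zeros((3, 3)))


def test_gate_requires_both_phenotypes_to_match():
    rng = np.random.default_rng(0)
    D = np.abs(rng.normal(size=(4, 4)))
    D = (D + D.T) / 2
    np.fill_diagonal(D, 0)
    pheno = _pheno(4, rng, sexes=["F", "M", "F", "F"],
                   apoes=["E4", "E4", "E3", "E4"])
    gate = phenotype_gate(pheno, D, knn=3)
    assert gate[0, 1] == 0          # sexes differ
    assert gate[0, 2] == 0          # apoe differs
    assert gate[0, 3] == 1          # both match, trivially within 3-NN
    assert np.all(np.diag(gate) == 0)
    assert np.allclose(gate, gate.T)


def test_gate_one_way_knn_suffices():
    # n = 40: j is i's 35th neighbor but i is j's 12th -> gated in (OR rule)
    n, knn = 40, 30
    D = np.zeros((n, n))
    # place subjects on a line so ranks are explicit
    pos = np.arange(n, dtype=float)
    pos[0] = 0.0
    D = np.abs(pos[:, None] - pos[None, :])
    # make subject 0 artificially far from everyone except j = 36
    D[0, 1:] += 100.0
    D[1:, 0] += 100.0
    D[0, 36] = D[36, 0] = 5.0
    pheno = _pheno(n, np.random.default_rng(1), sexes=["F"] * n,
                   apoes=["E3"] * n)
    gate = phenotype_gate(pheno, D, knn=knn)
    ranks_of_0_for_36 = np.argsort(D[36])  # includes self first
    assert gate[0, 36] == 1


def test_gate_missing_phenotype_named():
    D = np.array([[0.0, 1.0], [1.0, 0.0]])
    pheno = pd.DataFrame({"subject_id": ["a", "b"],
                          "sex": ["F", None], "apoe": ["E3", "E3"]})
    with pytest.raises(GraphError, match="b"):
        phenotype_gate(pheno, D, knn=1)


def test_adjacency_cases():
    Sim = np.array([[1.0, 0.5], [0.5, 1.0]])
    assert np.all(population_adjacency(Sim, np.zeros((2, 2))) == 0)
    with pytest.warns(UserWarning, match="isolated"):
        W = population_adjacency(Sim, np.zeros((2, 2)))
    gate = np.array([[0.0, 1.0], [1.0, 0.0]])
    W = population_adjacency(Sim, gate)
    assert W[0, 1] == 0.5 and W[0, 0] == 0.0


def test_gate_sparsity_bound():
    g = _blob_graph(n=30, knn=8)
    assert np.count_nonzero(g.W) <= 2 * 30 * 8


# ---------------------------------------------------------------------------
# Laplacian and Chebyshev convolution

def test_scaled_laplacian_two_nodes():
    W = np.array([[0.0, 1.0], [1.0, 0.0]])
    Lt = scaled_laplacian(W)
    assert np.allclose(Lt, [[0.0, -1.0], [-1.0, 0.0]], atol=1e-6)


def test_scaled_laplacian_empty_graph_is_identity():
    Lt = scaled_laplacian(np.zeros((4, 4)))
    assert np.allclose(Lt, np.eye(4))


@pytest.mark.parametrize("seed", range(4))
def test_scaled_laplacian_spectrum_in_unit_interval(seed):
    rng = np.random.default_rng(seed)
    W = np.abs(rng.normal(size=(15, 15)))
    W = (W + W.T) / 2
    np.fill_diagonal(W, 0)
    W[W < 0.8] = 0.0  # sparsify
    vals = np.linalg.eigvalsh(scaled_laplacian(W))
    assert vals.min() >= -1 - 1e-6 and vals.max() <= 1 + 1e-6


def test_cheb_conv_order_zero_no_mixing():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(6, 3))
    theta = rng.normal(size=(1, 3, 2))
    Lt = rng.normal(size=(6, 6))
    assert np.allclose(cheb_conv(Lt, X, theta, K=0), X @ theta[0])


def test_cheb_conv_zero_laplacian_chebyshev_values():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(5, 4))
    theta = rng.normal(size=(3, 4, 2))
    out = cheb_conv(np.zeros((5, 5)), X, theta, K=2)
    # T_0(0) = I, T_1(0) = 0, T_2(0) = -I
    assert np.allclose(out, X @ theta[0] - X @ theta[2])


def test_cheb_conv_permutation_equivariance():
    rng = np.random.default_rng(2)
    n = 12
    W = np.abs(rng.normal(size=(n, n)))
    W = (W + W.T) / 2
    np.fill_diagonal(W, 0)
    Lt = scaled_laplacian(W)
    X = rng.normal(size=(n, 5))
    theta = rng.normal(size=(3, 5, 4))
    perm = rng.permutation(n)
    P = np.eye(n)[perm]
    lhs = (P @ cheb_conv(Lt, X, theta, K=2))
    rhs = cheb_conv(P @ Lt @ P.T, P @ X, theta, K=2)
    assert np.allclose(lhs, rhs, atol=1e-10)


def test_cheb_recurrence_matches_polynomials():
    rng = np.random.default_rng(3)
    A = rng.normal(size=(6, 6))
    A = (A + A.T) / 2 / 10
    T = cheb_polynomials(A, 3)
    assert np.allclose(T[2], 2 * A @ A - np.eye(6))
    assert np.allclose(T[3], 4 * A @ A @ A - 3 * A)


# ---------------------------------------------------------------------------
# Training

def test_softmax_rows_sum_to_one():
    g = _blob_graph()
    cfg = GCNConfig(epochs=5, seed=0)
    _, probs = train_transductive(g, cfg, np.arange(g.n))
    assert np.abs(probs.sum(axis=1) - 1.0).max() < 1e-6


def test_isolated_graph_reduces_to_mlp_on_separable_blobs():
    g = _blob_graph(sep=6.0)
    g.W[:] = 0.0  # no edges at all
    cfg = GCNConfig(epochs=150, dropout=0.0, seed=1)
    _, probs = train_transductive(g, cfg, np.arange(g.n))
    assert np.mean(probs.argmax(axis=1) == g.labels) == 1.0


def test_seed_changes_weights_but_training_converges():
    g = _blob_graph(sep=5.0)
    train_idx = np.arange(0, g.n, 2)
    p1, probs1 = train_transductive(g, GCNConfig(epochs=80, seed=0),
                                    train_idx)
    p2, probs2 = train_transductive(g, GCNConfig(epochs=80, seed=1),
                                    train_idx)
    assert not np.array_equal(p1["theta0"], p2["theta0"])
    for probs in (probs1, probs2):
        acc = np.mean(probs[train_idx].argmax(axis=1) == g.labels[train_idx])
        assert acc > 0.9


def test_training_requires_all_classes():
    g = _blob_graph()
    with pytest.raises(GraphError):
        train_transductive(g, GCNConfig(epochs=1), np.arange(g.n // 2))


def test_training_deterministic_given_seed():
    g = _blob_graph()
    cfg = GCNConfig(epochs=20, seed=5)
    _, a = train_transductive(g, cfg, np.arange(g.n))
    _, b = train_transductive(g, cfg, np.arange(g.n))
    assert np.array_equal(a, b)


# ---------------------------------------------------------------------------
# Evaluation

def test_evaluate_split_arithmetic():
    # TP=3, FN=1, TN=4, FP=2
    labels = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
    pred = np.array([1, 1, 1, 0, 1, 1, 0, 0, 0, 0])
    probs = np.eye(2)[pred]
    res = evaluate_split(probs, labels, np.arange(10), positive_class=1)
    assert res.accuracy == pytest.approx(0.7)
    assert res.precision == pytest.approx(0.6)
    assert res.recall == pytest.approx(0.75)
    assert res.specificity == pytest.approx(2 / 3)


def test_evaluate_split_perfect():
    labels = np.array([0, 1, 0, 1])
    probs = np.eye(2)[labels]
    res = evaluate_split(probs, labels, np.arange(4))
    assert (res.accuracy, res.precision, res.recall, res.specificity) == \
        (1.0, 1.0, 1.0, 1.0)


def test_evaluate_split_no_positive_predictions():
    labels = np.array([1, 0, 0])
    probs = np.eye(2)[[0, 0, 0]]
    with pytest.warns(UserWarning, match="precision"):
        res = evaluate_split(probs, labels, np.arange(3))
    assert np.isnan(res.precision)
    assert res.specificity == 1.0


def test_evaluate_split_empty_test_set():
    with pytest.raises(GraphError):
        evaluate_split(np.eye(2), np.array([0, 1]), np.array([], dtype=int))


def test_stratified_split_proportions_within_one():
    rng = np.random.default_rng(0)
    labels = np.array([0] * 23 + [1] * 17)
    train, test = stratified_split(labels, 0.7, rng)
    assert len(set(train) & set(test)) == 0
    assert len(train) + len(test) == 40
    global_frac = 17 / 40
    for idx in (train, test):
        frac = np.mean(labels[idx] == 1)
        assert abs(frac * len(idx) - global_frac * len(idx)) <= 1.0


def test_monte_carlo_cv_deterministic():
    g = _blob_graph(n=24, sep=5.0)
    cfg = GCNConfig(epochs=30, seed=0)
    r1 = monte_carlo_cv(g, cfg, n_draws=3, train_fraction=0.7, seed=9)
    r2 = monte_carlo_cv(g, cfg, n_draws=3, train_fraction=0.7, seed=9)
    assert [d["accuracy"] for d in r1.per_draw] == \
        [d["accuracy"] for d in r2.per_draw]


def test_monte_carlo_cv_null_labels_at_chance():
    rng = np.random.default_rng(4)
    n = 30
    labels = np.array([0] * 15 + [1] * 15)
    X = rng.normal(size=(n, 4))                    # pure noise features
    D = np.linalg.norm(X[:, None] - X[None, :], axis=2)
    pheno = _pheno(n, rng, sexes=["F"] * n, apoes=["E3"] * n)
    g = build_population_graph(D, X, labels, pheno, knn=8)
    cfg = GCNConfig(epochs=60, seed=0)
    res = monte_carlo_cv(g, cfg, n_draws=8, train_fraction=0.7, seed=2)
    se = res.summary["accuracy"]["std"] / np.sqrt(8)
    assert abs(res.accuracy - 0.5) <= max(3 * se, 0.25)
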