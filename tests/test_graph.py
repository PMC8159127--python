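"""Neighborhood-graph construction and Laplacian invariants."""

import numpy as np
import pytest

from biodimred import DisconnectedGraphError, build_adjacency_graph


def _brute_force_graph(X, k, sigma):
    """Independent oracle: exhaustive pairwise kNN-union heat-kernel graph."""
    n = len(X)
    D2 = np.array([[np.sum((X[i] - X[j]) ** 2) for j in range(n)]
                   for i in range(n)])
    W = np.zeros((n, n))
    for i in range(n):
        dists = sorted(D2[i, j] for j in range(n) if j != i)
        kth = dists[k - 1]
        nbrs = [j for j in range(n) if j != i and D2[i, j] <= kth]
        for j in nbrs:
            w = np.exp(-D2[i, j] / (2 * sigma**2))
            W[i, j] = W[j, i] = w
    return W


def test_coincident_points_weight_one():
    X = np.array([[1.0, 1.0], [1.0, 1.0], [5.0, 5.0]])
    g = build_adjacency_graph(X, k=2, sigma=1.0)
    assert g.W[0, 1] == 1.0


def test_heat_kernel_closed_form():
    sigma = 0.7
    X = np.array([[0.0], [sigma * np.sqrt(2.0)], [3 * sigma * np.sqrt(2.0)]])
    g = build_adjacency_graph(X, k=2, sigma=sigma)
    np.testing.assert_allclose(g.W[0, 1], np.exp(-1.0), rtol=1e-12)


def test_line_graph_matches_brute_force_oracle():
    X = np.array([[0.0], [1.0], [2.5], [4.5], [7.0]])
    g = build_adjacency_graph(X, k=1, sigma=1.0)
    W_oracle = _brute_force_graph(X, k=1, sigma=1.0)
    np.testing.assert_allclose(g.W, W_oracle, atol=1e-12)


@pytest.mark.parametrize("trial", range(10))
def test_random_graphs_match_oracle(trial):
    rng = np.random.default_rng(trial)
    n = int(rng.integers(6, 15))
    X = rng.normal(size=(n, 3))
    k = int(rng.integers(1, n - 1))
    W_oracle = _brute_force_graph(X, k, 1.3)
    try:
        g = build_adjacency_graph(X, k=k, sigma=1.3)
        np.testing.assert_allclose(g.W, W_oracle, atol=1e-12)
    except DisconnectedGraphError:
        g = build_adjacency_graph(X, k=k, sigma=1.3,
                                  on_disconnected="largest")
        keep = g.node_indices
        np.testing.assert_allclose(g.W, W_oracle[np.ix_(keep, keep)],
                                   atol=1e-12)


def test_laplacian_invariants_over_random_graphs(rng):
    """L.1 = 0, W symmetric, L PSD for 100 random graphs."""
    for trial in range(100):
        n = int(rng.integers(5, 25))
        X = rng.normal(size=(n, int(rng.integers(2, 6))))
        k = int(rng.integers(1, n))
        try:
            g = build_adjacency_graph(X, k=k)
        except DisconnectedGraphError:
            g = build_adjacency_graph(X, k=k, on_disconnected="largest")
            if g.n < 3:
                continue
        assert np.allclose(g.W, g.W.T)
        assert np.all(np.diag(g.W) == 0)
        g.validate()  # row sums ~0 and PSD within tolerance


def test_epsilon_mode():
    X = np.array([[0.0], [1.0], [2.0], [10.0]])
    g = build_adjacency_graph(X, eps=1.5, sigma=1.0,
                              on_disconnected="largest")
    assert g.n == 3  # the far point is not within sqrt(1.5) of anything
    assert list(g.dropped) == [3]


def test_parameter_validation():
    X = np.random.default_rng(0).normal(size=(5, 2))
    with pytest.raises(ValueError, match="exactly one"):
        build_adjacency_graph(X, k=2, eps=1.0)
    with pytest.raises(ValueError, match="exactly one"):
        build_adjacency_graph(X)
    with pytest.raises(ValueError, match="k must"):
        build_adjacency_graph(X, k=5)
    with pytest.raises(ValueError, match="at least 3"):
        build_adjacency_graph(X[:2], k=1)


def test_disconnected_default_errors():
    X = np.vstack([np.zeros((3, 2)), 100.0 + np.zeros((3, 2))])
    X += np.random.default_rng(0).normal(scale=0.01, size=X.shape)
    with pytest.raises(DisconnectedGraphError):
        build_adjacency_graph(X, k=2)
    g = build_adjacency_graph(X, k=2, on_disconnected="largest")
    assert g.n == 3 and len(g.dropped) == 3
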