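"""Laplacian eigenmaps: dense-oracle equivalence, objective, transduction."""

import numpy as np
import pytest
import scipy.linalg

from biodimred import (
    DisconnectedGraphError,
    NeighborhoodGraph,
    build_adjacency_graph,
    embed_transductive_le,
    le_embed,
    le_objective,
)


def _dense_oracle(graph, m):
    """Independent oracle: direct dense generalized eigensolver of the
    graph eigenproblem (Laplacian vs degree matrix)."""
    vals, vecs = scipy.linalg.eigh(graph.L, graph.D)
    return vals[1 : m + 1], vecs[:, 1 : m + 1]


def _match_signs(A, B):
    """Align column signs of A to B (eigenvectors are sign-ambiguous)."""
    out = A.copy()
    for j in range(A.shape[1]):
        if np.dot(A[:, j], B[:, j]) < 0:
            out[:, j] = -A[:, j]
    return out


def _objective_brute(Y, graph):
    total = 0.0
    for i in range(graph.n):
        for j in range(graph.n):
            total += graph.W[i, j] * np.sum((Y[i] - Y[j]) ** 2)
    return total


def test_constant_vector_in_null_space(rng):
    X = rng.normal(size=(12, 3))
    g = build_adjacency_graph(X, k=4)
    ones = np.ones(g.n)
    np.testing.assert_allclose(g.L @ ones, 0.0, atol=1e-12)


def test_two_clusters_split_by_sign():
    rng = np.random.default_rng(5)
    a = rng.normal(scale=0.1, size=(8, 2))
    b = rng.normal(scale=0.1, size=(8, 2)) + [4.0, 0.0]
    X = np.vstack([a, b])
    g = build_adjacency_graph(X, k=8, sigma=1.0)
    emb = le_embed(g, 1)
    f1 = emb.Y[:, 0]
    assert set(np.sign(f1[:8])) == {np.sign(f1[0])}
    assert np.sign(f1[0]) == -np.sign(f1[8])
    # the oracle's first nontrivial eigenvector splits identically
    _, vec = _dense_oracle(g, 1)
    assert np.array_equal(np.sign(vec[:, 0] * vec[0, 0]),
                          np.sign(f1 * f1[0]))


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_embedding_matches_dense_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(8, 20))
    X = rng.normal(size=(n, 4))
    g = build_adjacency_graph(X, k=max(3, n // 2))
    m = 3
    emb = le_embed(g, m)
    vals, vecs = _dense_oracle(g, m)
    np.testing.assert_allclose(emb.eigvals, vals, atol=1e-8)
    np.testing.assert_allclose(_match_signs(vecs, emb.Y), emb.Y, atol=1e-8)


def test_embedding_is_d_orthonormal(rng):
    X = rng.normal(size=(15, 3))
    g = build_adjacency_graph(X, k=6)
    emb = le_embed(g, 4)
    gram = emb.Y.T @ np.diag(g.degrees) @ emb.Y
    np.testing.assert_allclose(gram, np.eye(4), atol=1e-6)


def test_appending_dimension_preserves_columns(rng):
    X = rng.normal(size=(14, 3))
    g = build_adjacency_graph(X, k=6)
    a = le_embed(g, 2)
    b = le_embed(g, 4)
    np.testing.assert_allclose(b.Y[:, :2], a.Y, atol=1e-9)
    assert np.all(np.diff(b.eigvals) >= -1e-12)


def test_disconnected_graph_rejected():
    W = np.zeros((6, 6))
    for i, j in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
        W[i, j] = W[j, i] = 0.9
    g = NeighborhoodGraph(W=W, sigma=1.0)
    with pytest.raises(DisconnectedGraphError):
        le_embed(g, 1)


def test_objective_zero_and_homogeneity(rng):
    X = rng.normal(size=(10, 2))
    g = build_adjacency_graph(X, k=4)
    same = np.ones((10, 2))
    assert abs(le_objective(same, g)) < 1e-12
    Y = rng.normal(size=(10, 2))
    np.testing.assert_allclose(le_objective(2 * Y, g),
                               4 * le_objective(Y, g), rtol=1e-12)
    np.testing.assert_allclose(le_objective(Y, g), _objective_brute(Y, g),
                               rtol=1e-10)


def test_eigenmap_minimizes_objective(rng):
    """The embedding must beat 100 random D-orthonormal competitors."""
    X = rng.normal(size=(12, 3))
    g = build_adjacency_graph(X, k=5)
    m = 2
    emb = le_embed(g, m)
    best = le_objective(emb.Y, g)
    d = g.degrees
    for _ in range(100):
        R = rng.normal(size=(12, m))
        # Gram-Schmidt in the D inner product
        for j in range(m):
            for i in range(j):
                R[:, j] -= (R[:, i] @ (d * R[:, j])) * R[:, i]
            R[:, j] /= np.sqrt(R[:, j] @ (d * R[:, j]))
        assert best <= le_objective(R, g) + 1e-9


def test_transductive_reduces_to_plain_embedding(rng):
    X = rng.normal(size=(12, 3))
    Ytr, Yte = embed_transductive_le(X, np.empty((0, 3)), k=5, m=2)
    g = build_adjacency_graph(X, k=5)
    np.testing.assert_allclose(Ytr, le_embed(g, 2).Y, atol=1e-12)
    assert Yte.shape == (0, 2)


def test_duplicated_point_coincides(rng):
    X = rng.normal(size=(12, 3))
    Ytr, Yte = embed_transductive_le(X, X[[4]], k=5, m=2)
    np.testing.assert_allclose(Ytr[4], Yte[0], atol=1e-8)


def test_transductive_cluster_membership_matches_oracle():
    rng = np.random.default_rng(9)
    a = rng.normal(scale=0.1, size=(6, 2))
    b = rng.normal(scale=0.1, size=(6, 2)) + [5.0, 0.0]
    test = np.vstack([a[:2] + 0.05, b[:2] + 0.05])
    train = np.vstack([a, b])
    Ytr, Yte = embed_transductive_le(train, test, k=8, sigma=2.0, m=1)
    g = build_adjacency_graph(np.vstack([train, test]), k=8, sigma=2.0)
    vals, vecs = scipy.linalg.eigh(g.L, g.D)
    f1 = vecs[:, 1]
    ref = np.sign(f1 * f1[0])
    got = np.sign(np.concatenate([Ytr[:, 0], Yte[:, 0]]))
    got = got * got[0] * ref[0]
    np.testing.assert_array_equal(got, ref)
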