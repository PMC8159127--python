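"""Three dimensionality-reduction methods with train/test semantics.

* **Laplacian eigenmaps (LE)** — nonlinear spectral embedding.  Build a
  neighborhood graph with heat-kernel weights
  ``w_ij = exp(-||x_i - x_j||^2 / (2 sigma^2))``, form the graph Laplacian
  ``L = D - W``, solve the generalized eigenproblem ``L f = lambda D f``,
  discard the constant eigenvector at ``lambda = 0`` and embed
  ``x_i -> (f_1(i), ..., f_m(i))`` with eigenvalues in ascending order.
  LE has no parametric out-of-sample map, so new points are handled
  *transductively*: train and test are re-embedded jointly
  (:func:`embed_transductive_le`).

* **Locality preserving projections (LPP)** — the linear analogue: solve
  ``X L X^T a = lambda X D X^T a`` on the training data; new points embed
  by the matrix product ``y = A^T x`` with no refitting.

* **Compressed-sensing random projection (CS)** — ``y = Phi x`` with an
  i.i.d. random measurement matrix ``Phi`` (M x N, M < N), used for
  classification, not signal reconstruction.  Gaussian entries are scaled
  by ``1/sqrt(M)`` so projections approximately preserve squared norms.

Numerical choices: generalized eigenproblems are solved via symmetric
reduction (``D^{-1/2} L D^{-1/2}`` for LE; ridge-stabilized ``X D X^T``
Cholesky form for LPP); eigenvector signs are fixed by making the
largest-absolute entry positive so repeated runs produce identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse
import scipy.sparse.linalg
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist

from ._rng import rng_from
from .records import PatternMatrix

__all__ = [
    "NeighborhoodGraph",
    "EmbeddingResult",
    "LPPModel",
    "CSProjector",
    "DisconnectedGraphError",
    "build_adjacency_graph",
    "le_embed",
    "le_objective",
    "lpp_fit",
    "lpp_transform",
    "cs_project",
    "embed_transductive_le",
]

#: above this node count LE switches from a dense to an iterative eigensolver
_DENSE_LIMIT = 1200


class DisconnectedGraphError(ValueError):
    """The neighborhood graph has more than one connected component."""


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, PatternMatrix):
        return X.X
    return np.atleast_2d(np.asarray(X, dtype=float))


# ---------------------------------------------------------------------------
# graph construction
# ---------------------------------------------------------------------------

@dataclass
class NeighborhoodGraph:
    """Heat-kernel weighted neighborhood graph and its Laplacian.

    ``W`` is symmetric with zero diagonal and entries in [0, 1]; ``D`` is
    the diagonal degree matrix ``d_ii = sum_j w_ij``; ``L = D - W`` is
    positive semidefinite with the constant vector in its null space.
    ``node_indices`` maps graph nodes back to input rows when the graph
    was restricted to the largest connected component.
    """

    W: np.ndarray
    sigma: float
    k: int | None = None
    eps: float | None = None
    node_indices: np.ndarray | None = None
    dropped: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("W must be square")
        if not np.allclose(W, W.T, atol=1e-12):
            raise ValueError("W must be symmetric")
        if np.any(np.diag(W) != 0):
            raise ValueError("W must have a zero diagonal")
        if W.min() < 0 or W.max() > 1 + 1e-12:
            raise ValueError("weights must lie in [0, 1]")
        self.W = W

    @property
    def n(self) -> int:
        return self.W.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return self.W.sum(axis=1)

    @property
    def D(self) -> np.ndarray:
        return np.diag(self.degrees)

    @property
    def L(self) -> np.ndarray:
        return np.diag(self.degrees) - self.W

    def is_connected(self) -> bool:
        ncomp, _ = connected_components(
            scipy.sparse.csr_matrix(self.W > 0), directed=False
        )
        return ncomp == 1

    def validate(self, psd_tol_scale: float = 1e-8) -> None:
        """Check the Laplacian invariants; raises ``AssertionError``."""
        L = self.L
        row_sums = L.sum(axis=1)
        assert np.max(np.abs(row_sums)) < 1e-10 * max(1.0, self.degrees.max()), (
            "Laplacian rows must sum to 0"
        )
        eigmin = scipy.linalg.eigvalsh(L, subset_by_index=(0, 0))[0]
        assert eigmin > -psd_tol_scale * max(np.trace(L), 1.0), (
            f"Laplacian must be PSD, min eigenvalue {eigmin}"
        )


def build_adjacency_graph(
    X,
    k: int | None = None,
    eps: float | None = None,
    sigma: float | str = "auto",
    on_disconnected: str = "error",
) -> NeighborhoodGraph:
    """Construct the heat-kernel neighborhood graph of a pattern set.

    Exactly one of ``k`` (symmetrized k-nearest-neighbor rule: edge (i, j)
    present iff j is among i's k nearest neighbors *or* vice versa,
    Euclidean metric; distance ties at the k-th neighbor are all included)
    and ``eps`` (edge iff ``||x_i - x_j||^2 < eps``) must be given.  Edge weights are ``exp(-||x_i-x_j||^2 / (2 sigma^2))``;
    ``sigma="auto"`` uses the median distance among connected pairs.

    ``on_disconnected`` is ``"error"`` (default) or ``"largest"`` to embed
    only the giant component, recording dropped node indices.
    """
    M = _as_matrix(X)
    n = M.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 patterns, got {n}")
    if (k is None) == (eps is None):
        raise ValueError("exactly one of k and eps must be given")

    D2 = cdist(M, M, metric="sqeuclidean")
    if k is not None:
        if not 1 <= k < n:
            raise ValueError(f"k must satisfy 1 <= k < n; got k={k}, n={n}")
        D2_search = D2.copy()
        np.fill_diagonal(D2_search, np.inf)  # a point is not its own neighbor
        # tie-inclusive rule: every point at the k-th-nearest distance is a
        # neighbor, so coincident points always share neighborhoods
        kth = np.sort(D2_search, axis=1)[:, k - 1]
        adj = D2_search <= kth[:, None]
        adj |= adj.T
    else:
        if eps <= 0:
            raise ValueError("eps must be positive")
        adj = D2 < eps
        np.fill_diagonal(adj, False)

    if sigma == "auto":
        pair_d = np.sqrt(D2[adj])
        sigma_val = float(np.median(pair_d)) if pair_d.size else 1.0
        if sigma_val == 0.0:
            sigma_val = 1.0
    else:
        sigma_val = float(sigma)
        if sigma_val <= 0:
            raise ValueError("sigma must be positive")

    W = np.where(adj, np.exp(-D2 / (2.0 * sigma_val**2)), 0.0)
    W = 0.5 * (W + W.T)
    np.fill_diagonal(W, 0.0)

    ncomp, comp = connected_components(
        scipy.sparse.csr_matrix(adj), directed=False
    )
    node_indices = None
    dropped = np.array([], dtype=int)
    if ncomp > 1:
        if on_disconnected == "largest":
            sizes = np.bincount(comp)
            keep = np.flatnonzero(comp == np.argmax(sizes))
            dropped = np.flatnonzero(comp != np.argmax(sizes))
            W = W[np.ix_(keep, keep)]
            node_indices = keep
        else:
            raise DisconnectedGraphError(
                f"neighborhood graph has {ncomp} connected components; "
                "increase k/eps or pass on_disconnected='largest'"
            )
    return NeighborhoodGraph(
        W=W, sigma=sigma_val, k=k, eps=eps,
        node_indices=node_indices, dropped=dropped,
    )


# ---------------------------------------------------------------------------
# Laplacian eigenmaps
# ---------------------------------------------------------------------------

@dataclass
class EmbeddingResult:
    """Per-pattern coordinates in ``m`` dimensions.

    For LE/LPP, ``eigvals`` are the generalized eigenvalues of the kept
    components in ascending order (the trivial ``lambda = 0`` eigenvector
    is excluded for LE); CS has no spectrum and stores an empty array.
    """

    Y: np.ndarray
    eigvals: np.ndarray
    method: str
    m: int

    def __post_init__(self) -> None:
        self.Y = np.atleast_2d(np.asarray(self.Y, dtype=float))
        self.eigvals = np.asarray(self.eigvals, dtype=float)
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.eigvals.size and np.any(np.diff(self.eigvals) < -1e-10):
            raise ValueError("eigenvalues must be non-decreasing")


def _fix_signs(vecs: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-absolute entry is positive."""
    vecs = vecs.copy()
    idx = np.argmax(np.abs(vecs), axis=0)
    signs = np.sign(vecs[idx, np.arange(vecs.shape[1])])
    signs[signs == 0] = 1.0
    return vecs * signs


def le_embed(graph: NeighborhoodGraph, m: int) -> EmbeddingResult:
    """Solve ``L f = lambda D f`` and embed on the first ``m`` nontrivial
    eigenvectors.

    Uses the symmetric reduction ``C = D^{-1/2} L D^{-1/2}`` (dense solver
    for small graphs, shift-invert Lanczos beyond ``_DENSE_LIMIT`` nodes).
    The constant eigenvector at ``lambda = 0`` is discarded; a repeated
    zero eigenvalue means the graph is disconnected and raises
    :class:`DisconnectedGraphError`.  Coordinates are D-orthonormal with
    the sign of each column fixed deterministically.
    """
    n = graph.n
    if not 1 <= m <= n - 2:
        raise ValueError(f"m must satisfy 1 <= m <= n-2; got m={m}, n={n}")
    d = graph.degrees
    if np.any(d <= 0):
        raise DisconnectedGraphError("graph has isolated (degree-0) nodes")

    dinv = 1.0 / np.sqrt(d)
    C = dinv[:, None] * graph.L * dinv[None, :]
    C = 0.5 * (C + C.T)

    k = m + 1
    if n <= _DENSE_LIMIT:
        vals, g = scipy.linalg.eigh(C, subset_by_index=(0, k - 1))
    else:
        try:
            vals, g = scipy.sparse.linalg.eigsh(
                scipy.sparse.csr_matrix(C), k=k, sigma=-1e-3, which="LM"
            )
        except scipy.sparse.linalg.ArpackNoConvergence as exc:
            raise RuntimeError("LE eigensolver did not converge") from exc
        order = np.argsort(vals)
        vals, g = vals[order], g[:, order]

    scale = max(vals[-1], 1.0)
    if vals[1] < 1e-9 * scale:
        raise DisconnectedGraphError(
            "zero eigenvalue has multiplicity > 1: graph is disconnected"
        )
    f = dinv[:, None] * g          # D-orthonormal generalized eigenvectors
    f = _fix_signs(f)
    return EmbeddingResult(
        Y=f[:, 1 : m + 1], eigvals=np.clip(vals[1 : m + 1], 0.0, None),
        method="le", m=m,
    )


def le_objective(Y, graph: NeighborhoodGraph) -> float:
    """Locality cost ``sum_ij ||y_i - y_j||^2 w_ij`` (symmetric double sum).

    Every ordered pair (i, j) contributes, i.e. each unordered pair is
    counted twice, matching the symmetric double sum; equals
    ``2 tr(Y^T L Y)``.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] != graph.n:
        raise ValueError(
            f"Y has {Y.shape[0]} rows for a graph of {graph.n} nodes"
        )
    return float(2.0 * np.einsum("im,ij,jm->", Y, graph.L, Y))


def embed_transductive_le(
    X_train,
    X_test,
    k: int = 10,
    sigma: float | str = "auto",
    m: int = 2,
    eps: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Jointly embed train and test patterns (LE has no out-of-sample map).

    One graph is built on the union; coordinates are split back in input
    order.  Test labels are never consulted.  With an empty test set this
    reduces exactly to ``le_embed`` on the training data.
    """
    A = _as_matrix(X_train)
    B = _as_matrix(X_test)
    if B.size == 0:
        graph = build_adjacency_graph(A, k=k, eps=eps, sigma=sigma)
        return le_embed(graph, m).Y, np.empty((0, m))
    if A.shape[1] != B.shape[1]:
        raise ValueError("train and test must share the feature count")
    union = np.vstack([A, B])
    graph = build_adjacency_graph(union, k=k, eps=eps, sigma=sigma)
    Y = le_embed(graph, m).Y
    return Y[: A.shape[0]], Y[A.shape[0] :]


# ---------------------------------------------------------------------------
# locality preserving projections
# ---------------------------------------------------------------------------

@dataclass
class LPPModel:
    """Linear projection ``y = A^T x`` learned on training data.

    ``A`` is ``p x l`` with columns ordered by ascending generalized
    eigenvalue ``lambda_0 < ... < lambda_{l-1}``.
    """

    A: np.ndarray
    eigvals: np.ndarray
    ridge: float

    def __post_init__(self) -> None:
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        self.eigvals = np.asarray(self.eigvals, dtype=float)
        if self.A.shape[1] > self.A.shape[0]:
            raise ValueError("target dimension l must not exceed p")
        if np.any(np.diff(self.eigvals) < -1e-10):
            raise ValueError("eigenvalues must be ascending")

    @property
    def l(self) -> int:
        return self.A.shape[1]


def lpp_fit(
    X,
    graph: NeighborhoodGraph,
    l: int,
    ridge: float | None = None,
    energy: float = 0.98,
) -> LPPModel:
    """Solve ``X L X^T a = lambda (X D X^T + ridge I) a`` on training rows.

    ``X`` holds patterns as rows (the data matrix of the eigenproblem is
    its transpose).  The problem is solved in a principal subspace of the
    training patterns retaining an ``energy`` fraction of their squared
    norm (default 0.98, the customary PCA step of LPP) and mapped back:
    this both removes the trivial null directions that arise when the
    feature count exceeds the data rank and keeps the smallest-eigenvalue
    directions from chasing noise.  ``energy=1.0`` keeps the full
    numerical rank; ``l`` may not exceed the retained rank.
    ``ridge=None`` uses the default ``1e-8 * trace(X D X^T) / p``; an
    explicit ``ridge=0`` with a singular right-hand matrix raises an
    error advising regularization.
    """
    M = _as_matrix(X)
    n, p = M.shape
    if graph.n != n:
        raise ValueError(f"graph has {graph.n} nodes for {n} patterns")
    if not 1 <= l <= p:
        raise ValueError(f"l must satisfy 1 <= l <= p; got l={l}, p={p}")
    if not 0.0 < energy <= 1.0:
        raise ValueError("energy must lie in (0, 1]")
    Xc = M.T  # p x n, columns are patterns
    d = graph.degrees

    # orthonormal basis of the (energy-truncated) data span
    U, s, _ = scipy.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > 1e-10 * (s[0] if s.size else 1.0)))
    if energy < 1.0 and rank > 1:
        cum = np.cumsum(s[:rank] ** 2) / np.sum(s[:rank] ** 2)
        energy_rank = int(np.searchsorted(cum, energy)) + 1
        rank = min(rank, max(energy_rank, min(l, rank)))
    if l > rank:
        raise ValueError(f"l={l} exceeds the retained data rank {rank}")
    U = U[:, :rank]
    B = U.T @ Xc  # rank x n, patterns expressed in the span basis

    SL = B @ graph.L @ B.T
    SD = (B * d[None, :]) @ B.T
    SL = 0.5 * (SL + SL.T)
    SD = 0.5 * (SD + SD.T)
    if ridge is None:
        ridge = 1e-8 * np.trace(SD) / p
    SDr = SD + ridge * np.eye(rank)
    try:
        scipy.linalg.cholesky(SDr)
    except scipy.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "X D X^T (+ridge) is singular; pass a positive ridge to regularize"
        ) from exc
    vals, vecs = scipy.linalg.eigh(SL, SDr, subset_by_index=(0, l - 1))
    return LPPModel(A=_fix_signs(U @ vecs), eigvals=vals, ridge=float(ridge))


def lpp_transform(model: LPPModel, Xnew) -> EmbeddingResult:
    """Embed new patterns by ``y_i = A^T x_i``; no refitting is needed."""
    M = _as_matrix(Xnew)
    if M.shape[1] != model.A.shape[0]:
        raise ValueError(
            f"patterns have {M.shape[1]} features, model expects "
            f"{model.A.shape[0]}"
        )
    return EmbeddingResult(
        Y=M @ model.A, eigvals=model.eigvals, method="lpp", m=model.l
    )


# ---------------------------------------------------------------------------
# compressed-sensing random projections
# ---------------------------------------------------------------------------

@dataclass
class CSProjector:
    """Random measurement matrix ``Phi`` (M x N) with its generating seed."""

    Phi: np.ndarray
    M: int
    N: int
    seed: int
    dist: str

    def transform(self, Xnew) -> EmbeddingResult:
        """Apply the same ``Phi`` to new rows: ``y = Phi x``."""
        A = _as_matrix(Xnew)
        if A.shape[1] != self.N:
            raise ValueError(
                f"patterns have {A.shape[1]} features, projector expects {self.N}"
            )
        return EmbeddingResult(
            Y=A @ self.Phi.T, eigvals=np.empty(0), method="cs", m=self.M
        )


def cs_project(
    X, M: int, seed: int = 0, dist: str = "gaussian"
) -> tuple[EmbeddingResult, CSProjector]:
    """Project patterns onto ``M`` random measurements, ``y = Phi x``.

    ``Phi`` is drawn once from the seed — i.i.d. Gaussian entries scaled
    by ``1/sqrt(M)`` (norm-preserving in expectation) or symmetric
    Bernoulli ``±1/sqrt(M)`` — and the returned projector applies the
    identical matrix to any later test rows.
    """
    A = _as_matrix(X)
    N = A.shape[1]
    if M >= N:
        raise ValueError(f"M must be < N; got M={M}, N={N}")
    if M < 1:
        raise ValueError("M must be >= 1")
    rng = rng_from(seed)
    if dist == "gaussian":
        Phi = rng.standard_normal((M, N)) / np.sqrt(M)
    elif dist == "bernoulli":
        Phi = (2.0 * rng.integers(0, 2, size=(M, N)) - 1.0) / np.sqrt(M)
    else:
        raise ValueError(f"dist must be 'gaussian' or 'bernoulli', got {dist!r}")
    proj = CSProjector(Phi=Phi, M=M, N=N, seed=int(seed), dist=dist)
    return proj.transform(A), proj
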