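"""Semi-supervised discriminant analysis (SDA) and a PCA baseline.

SDA augments two-class LDA with a graph-smoothness regularizer built
from labeled *and* unlabeled samples.  With between-class scatter S_b,
total scatter S_t (labeled points only) and the p-nearest-neighbor graph
Laplacian L = D - S over all points X, the projection directions solve

    S_b a = lambda (S_t + beta X L X^T + eps I) a,

keeping the top-c eigenvectors (c = 2 classes here).  The labeled points
pull classes apart; the unlabeled points only shape the Laplacian term,
which penalizes projections that vary across graph edges.

Deep features are ~48,400-dimensional while there are only tens of
training samples, so the d x d matrices are never materialized: every
projection direction with a nonzero objective lies in the span of the
training points, and the eigenproblem is solved in an orthonormal basis
of that span (rank <= N), which is mathematically equivalent.  A direct
d x d solver is kept for low-dimensional cross-checking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .errors import DataError, NumericalError, ParameterError

__all__ = [
    "AffinityGraph",
    "ScatterSet",
    "SDAModel",
    "build_affinity_graph",
    "scatter_matrices",
    "fit_sda",
    "transform",
    "fit_pca",
]


@dataclass
class AffinityGraph:
    S: np.ndarray  # (N, N) symmetric 0/1, zero diagonal
    D: np.ndarray  # diagonal degree matrix
    L: np.ndarray  # Laplacian D - S
    p: int


@dataclass
class ScatterSet:
    S_b: np.ndarray
    S_w: np.ndarray
    S_t: np.ndarray
    class_means: dict
    mean: np.ndarray
    counts: dict


@dataclass
class SDAModel:
    A: np.ndarray  # (d, c) projection basis, unit-norm columns
    eigenvalues: np.ndarray  # descending
    beta: float
    p: int
    ridge: float
    classes: np.ndarray
    residual: float  # relative eigen-residual certificate


def build_affinity_graph(X: np.ndarray, p: int) -> AffinityGraph:
    """0/1 p-nearest-neighbor graph, symmetrized by OR, plus its Laplacian."""
    X = np.asarray(X, dtype=np.float64)
    n = len(X)
    if p < 1:
        raise ParameterError(f"p must be >= 1, got {p}")
    if p >= n:
        raise ParameterError(f"p={p} requires at least p+1={p + 1} points, got {n}")
    nn = NearestNeighbors(n_neighbors=p + 1).fit(X)
    _, idx = nn.kneighbors(X)
    S = np.zeros((n, n))
    rows = np.repeat(np.arange(n), p + 1)
    S[rows, idx.ravel()] = 1.0
    np.fill_diagonal(S, 0.0)
    S = np.maximum(S, S.T)  # x_i in N_p(x_j) OR x_j in N_p(x_i)
    D = np.diag(S.sum(axis=1))
    return AffinityGraph(S=S, D=D, L=D - S, p=p)


def scatter_matrices(X: np.ndarray, y: np.ndarray) -> ScatterSet:
    """Between-, within- and total-scatter matrices of the labeled data.

    S_b = sum_k N_k (mu_k - mu)(mu_k - mu)^T,
    S_w = sum_k sum_i (x_i - mu_k)(x_i - mu_k)^T,
    S_t = sum_i (x_i - mu)(x_i - mu)^T = S_b + S_w.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise DataError("scatter matrices need at least two classes")
    mu = X.mean(axis=0)
    d = X.shape[1]
    S_b = np.zeros((d, d))
    S_w = np.zeros((d, d))
    class_means, counts = {}, {}
    for k in classes:
        Xk = X[y == k]
        mk = Xk.mean(axis=0)
        class_means[k], counts[k] = mk, len(Xk)
        dm = mk - mu
        S_b += len(Xk) * np.outer(dm, dm)
        C = Xk - mk
        S_w += C.T @ C
    C = X - mu
    S_t = C.T @ C
    if not np.allclose(S_t, S_b + S_w, atol=1e-8 * max(1.0, np.abs(S_t).max())):
        raise NumericalError("scatter identity S_t = S_b + S_w violated")
    return ScatterSet(S_b=S_b, S_w=S_w, S_t=S_t, class_means=class_means, mean=mu, counts=counts)


def _solve_sda_small(
    X_l: np.ndarray,
    y: np.ndarray,
    X_all: np.ndarray,
    beta: float,
    p: int,
    ridge_scale: float,
    n_components: int,
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Dense generalized eigensolve in the given (possibly reduced) space."""
    sc = scatter_matrices(X_l, y)
    if beta > 0 and len(X_all) > p:
        L = build_affinity_graph(X_all, p).L
        reg = X_all.T @ L @ X_all
    else:
        reg = np.zeros_like(sc.S_t)
    denom = sc.S_t + beta * reg
    rank = max(1, min(denom.shape[0], len(X_all)))
    eps = ridge_scale * np.trace(denom) / rank
    if eps <= 0:
        eps = ridge_scale
    denom = denom + eps * np.eye(denom.shape[0])
    try:
        w, V = scipy.linalg.eigh(sc.S_b, denom)
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover
        raise NumericalError(f"generalized eigensolve failed: {exc}") from exc
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]

    # S_b has rank <= c-1, so only the informative eigenpairs (lambda
    # clearly above the noise floor) are taken from the pencil; the
    # remaining directions are completed deterministically by maximizing
    # total scatter subject to M-orthogonality to the chosen columns.
    # This makes the returned basis independent of the working basis,
    # i.e. identical (up to sign) for the span and direct solvers.
    tol = max(1e-9 * max(w.max(), 0.0), 1e-300)
    keep = [V[:, j] for j in range(min(n_components, V.shape[1])) if w[j] > tol]
    lams = [w[j] for j in range(len(keep))]
    dim = denom.shape[0]
    while len(keep) < min(n_components, dim):
        if keep:
            C = (denom @ np.column_stack(keep)).T
            Nb = scipy.linalg.null_space(C)
        else:
            Nb = np.eye(dim)
        wt, Vt = scipy.linalg.eigh(Nb.T @ sc.S_t @ Nb, Nb.T @ denom @ Nb)
        a = Nb @ Vt[:, -1]
        keep.append(a)
        lams.append(float(a @ sc.S_b @ a / (a @ denom @ a)))
    V = np.column_stack(keep)
    w = np.asarray(lams)

    # backward-error certificate ||S_b a - lambda M a|| relative to the
    # operator scale; for informative pairs this implies the tighter
    # ||S_b a - lambda M a|| <= tol ||S_b a|| form
    scale = np.linalg.norm(sc.S_b) + np.abs(w).max() * np.linalg.norm(denom)
    scale = max(scale, np.finfo(float).tiny)
    res = 0.0
    for lam, a in zip(w, V.T):
        r = np.linalg.norm(sc.S_b @ a - lam * (denom @ a)) / (scale * np.linalg.norm(a))
        res = max(res, r)
    return w, V, eps, res


def fit_sda(
    X_labeled: np.ndarray,
    y: np.ndarray,
    X_unlabeled: np.ndarray | None = None,
    beta: float = 1.0,
    p: int = 5,
    ridge_scale: float = 1e-6,
    n_components: int = 2,
    solver: str = "auto",
) -> SDAModel:
    """Fit the SDA projection.

    Parameters
    ----------
    X_labeled, y : labeled training features and class labels.
    X_unlabeled : rows that only participate in the neighbor graph.
    beta : weight of the graph-smoothness regularizer (0 recovers LDA).
    p : neighbor count of the affinity graph.
    ridge_scale : the ridge added to the denominator matrix is
        ridge_scale * trace(S_t + beta X L X^T) / rank.
    solver : 'span' (solve in the span of the training points; required
        when d >> N), 'direct' (dense d x d), or 'auto'.
    """
    X_labeled = np.asarray(X_labeled, dtype=np.float64)
    y = np.asarray(y)
    if beta < 0:
        raise ParameterError(f"beta must be >= 0, got {beta}")
    classes = np.unique(y)
    if len(classes) < 2:
        raise DataError("labeled set must contain both classes")
    if X_unlabeled is None or len(X_unlabeled) == 0:
        X_all = X_labeled
    else:
        X_unlabeled = np.asarray(X_unlabeled, dtype=np.float64)
        if X_unlabeled.shape[1] != X_labeled.shape[1]:
            raise DataError("labeled/unlabeled dimensionality mismatch")
        X_all = np.vstack([X_labeled, X_unlabeled])
    d = X_labeled.shape[1]
    if solver == "auto":
        solver = "direct" if d <= max(64, len(X_all)) else "span"
    if solver not in ("direct", "span"):
        raise ParameterError(f"unknown solver {solver!r}")

    if solver == "direct":
        w, V, eps, res = _solve_sda_small(
            X_labeled, y, X_all, beta, p, ridge_scale, n_components
        )
        A = V
    else:
        # orthonormal basis of the span of all training points (and their
        # mean, which lies in the span); rank r <= N
        Q = scipy.linalg.orth(X_all.T)  # (d, r)
        C_l = X_labeled @ Q
        C_all = X_all @ Q
        w, V, eps, res = _solve_sda_small(C_l, y, C_all, beta, p, ridge_scale, n_components)
        A = Q @ V

    # unit-norm columns with the largest-magnitude entry positive
    for j in range(A.shape[1]):
        nrm = np.linalg.norm(A[:, j])
        if nrm > 0:
            A[:, j] /= nrm
        if A[np.argmax(np.abs(A[:, j])), j] < 0:
            A[:, j] *= -1.0
    return SDAModel(
        A=A, eigenvalues=w, beta=beta, p=p, ridge=eps, classes=classes, residual=res
    )


def transform(model: SDAModel, X: np.ndarray) -> np.ndarray:
    """Embed rows of X as z = A^T x."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[None]
    if X.shape[1] != model.A.shape[0]:
        raise DataError(
            f"expected {model.A.shape[0]}-dimensional rows, got {X.shape[1]}"
        )
    return X @ model.A


def fit_pca(X: np.ndarray, k: int) -> PCA:
    """Top-k principal directions of the centered data (baseline reducer)."""
    X = np.asarray(X, dtype=np.float64)
    if not 1 <= k <= min(len(X) - 1, X.shape[1]):
        raise ParameterError(
            f"k={k} must be in [1, min(N-1, d)] = [1, {min(len(X) - 1, X.shape[1])}]"
        )
    return PCA(n_components=k, svd_solver="full").fit(X)
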