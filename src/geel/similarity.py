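"""k-mer spectrum features and linear-neighborhood similarity (LNS).

Each sequence is summarized by its k-spectrum (counts of all 4^k length-k
substrings, overlaps included; k=5 by default).  Similarity between entities
of one kind is then defined by linear neighborhood reconstruction: the row of
weights that best rebuilds an entity's (L2-normalized) spectrum as a convex
combination of its kappa nearest neighbors' spectra,

    min_w ||x_i - sum_{j in N(i)} w_j x_j||^2 + lam ||w||^2
    s.t.  w_j >= 0,  sum_j w_j = 1,

so each similarity row is a probability vector supported on the neighborhood.
The top-``n_neighbors`` entries per row (default 10) are kept and
max-symmetrized to form the kNN graph blocks of the heterogeneous network.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator, TransformerMixin

_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}


@dataclasses.dataclass
class KmerSpectrum:
    entity_id: str
    k: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.size != 4 ** self.k:
            raise ValueError(f"spectrum for {self.entity_id} has {self.counts.size} bins, expected {4 ** self.k}")


def kmer_index(kmer: str) -> int:
    """Lexicographic index of a k-mer over the alphabet ACGU."""
    idx = 0
    for ch in kmer:
        idx = idx * 4 + _CODE[ch]
    return idx


def kmer_spectrum(seq, k: int = 5) -> KmerSpectrum:
    """Count all overlapping k-mers of a sequence record.

    Accepts a ``SequenceRecord``-like object (``.id``, ``.residues``) or a
    plain string.  Invariant: counts sum to len(seq) - k + 1.
    """
    if hasattr(seq, "residues"):
        sid, residues = seq.id, seq.residues
    else:
        sid, residues = "<anon>", str(seq)
    n = len(residues)
    if n < k:
        raise ValueError(f"sequence {sid!r} has length {n} < k={k}")
    codes = np.array([_CODE[c] for c in residues], dtype=np.int64)
    # rolling base-4 encoding of each window
    weights = 4 ** np.arange(k - 1, -1, -1)
    idx = np.convolve(codes, weights[::-1], mode="valid") if k > 1 else codes
    counts = np.bincount(idx, minlength=4 ** k)
    return KmerSpectrum(entity_id=sid, k=k, counts=counts)


def spectrum_matrix(records, k: int = 5, normalize: bool = True) -> np.ndarray:
    """Stack spectra into an n x 4^k float matrix, L2-normalizing rows by
    default (removes the lncRNA/miRNA length disparity before distances)."""
    X = np.stack([kmer_spectrum(rec, k).counts for rec in records]).astype(float)
    if normalize:
        norms = np.linalg.norm(X, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        X = X / norms
    return X


def _solve_simplex_qp(x: np.ndarray, XN: np.ndarray, lam: float) -> np.ndarray:
    """min ||x - XN.T w||^2 + lam ||w||^2 over the probability simplex.

    Small dense QP (kappa variables); solved by SLSQP with analytic
    gradient from the precomputed Gram form.
    """
    kappa = XN.shape[0]
    G = XN @ XN.T + lam * np.eye(kappa)
    c = XN @ x
    w0 = np.full(kappa, 1.0 / kappa)

    def fun(w):
        return float(w @ G @ w - 2 * c @ w)

    def jac(w):
        return 2 * (G @ w - c)

    res = minimize(
        fun,
        w0,
        jac=jac,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * kappa,
        constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0, "jac": lambda w: np.ones(kappa)}],
        options={"maxiter": 200, "ftol": 1e-12},
    )
    w = np.clip(res.x, 0.0, None)
    s = w.sum()
    return w / s if s > 0 else np.full(kappa, 1.0 / kappa)


def lns_similarity(X: np.ndarray, kappa: int = 10, lam: float = 1e-6) -> np.ndarray:
    """Linear-neighborhood similarity matrix from feature rows X (n x d).

    Row i carries the optimal reconstruction weights of entity i over its
    ``kappa`` Euclidean-nearest neighbors; zeros elsewhere.  Rows are
    nonnegative with unit sum and zero diagonal.  Degenerate all-identical
    neighborhoods fall back to uniform weights 1/kappa.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 entities")
    if not (1 <= kappa < n):
        raise ValueError(f"kappa must satisfy 1 <= kappa < n={n}, got {kappa}")
    d2 = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=-1) if n <= 2000 else None
    if d2 is None:  # pragma: no cover - large-n path, same semantics
        sq = np.einsum("ij,ij->i", X, X)
        d2 = sq[:, None] + sq[None, :] - 2 * X @ X.T
    np.fill_diagonal(d2, np.inf)
    S = np.zeros((n, n))
    for i in range(n):
        # stable argsort => ties broken by lower index
        nbrs = np.argsort(d2[i], kind="stable")[:kappa]
        XN = X[nbrs]
        if np.allclose(XN, XN[0], atol=1e-12) and np.allclose(XN[0], X[i], atol=1e-12):
            w = np.full(kappa, 1.0 / kappa)
        else:
            w = _solve_simplex_qp(X[i], XN, lam)
        S[i, nbrs] = w
    np.fill_diagonal(S, 0.0)
    return S


def topk_neighbor_graph(S: np.ndarray, n_neighbors: int = 10) -> np.ndarray:
    """Sparsify a similarity matrix to its top-k neighbors per row, then
    symmetrize by elementwise maximum with the transpose.

    Per row the ``n_neighbors`` largest off-diagonal entries are kept (ties
    broken by lower column index).  ``n_neighbors >= n`` keeps every
    off-diagonal entry with a warning.
    """
    S = np.asarray(S, dtype=float)
    n = S.shape[0]
    if n_neighbors < 1:
        raise ValueError("n_neighbors must be >= 1")
    if n_neighbors >= n:
        warnings.warn(f"n_neighbors={n_neighbors} >= n={n}; keeping all off-diagonal entries")
        n_neighbors = n - 1
    W = np.zeros_like(S)
    for i in range(n):
        row = S[i].copy()
        row[i] = -np.inf
        # stable sort on (-value, index): largest values first, lower index on ties
        order = np.argsort(-row, kind="stable")[:n_neighbors]
        keep = order[row[order] > 0]
        W[i, keep] = S[i, keep]
    W = np.maximum(W, W.T)
    np.fill_diagonal(W, 0.0)
    return W


class LinearNeighborhoodSimilarity(BaseEstimator, TransformerMixin):
    """Estimator wrapper: k-spectrum -> LNS similarity -> top-k neighbor graph.

    Parameters
    ----------
    k : spectrum k-mer size (5 in the standard construction).
    kappa : LNS reconstruction neighborhood size.
    lam : ridge term of the per-row QP, for numerical stability.
    n_neighbors : neighbors kept per row of the output graph (10 in the
        standard construction).
    symmetrize : max-symmetrize the kNN graph (kept as a flag because the
        row-wise construction is inherently directed).

    Attributes
    ----------
    similarity_ : dense LNS matrix S (rows on the probability simplex).
    graph_ : sparsified, optionally symmetrized kNN graph W.
    """

    def __init__(self, k: int = 5, kappa: int = 10, lam: float = 1e-6, n_neighbors: int = 10, symmetrize: bool = True):
        self.k = k
        self.kappa = kappa
        self.lam = lam
        self.n_neighbors = n_neighbors
        self.symmetrize = symmetrize

    def fit(self, records, y=None):
        X = spectrum_matrix(records, k=self.k)
        kappa = min(self.kappa, X.shape[0] - 1)
        self.similarity_ = lns_similarity(X, kappa=kappa, lam=self.lam)
        if self.symmetrize:
            self.graph_ = topk_neighbor_graph(self.similarity_, self.n_neighbors)
        else:
            n = X.shape[0]
            k_eff = min(self.n_neighbors, n - 1)
            W = np.zeros_like(self.similarity_)
            for i in range(n):
                row = self.similarity_[i].copy()
                row[i] = -np.inf
                order = np.argsort(-row, kind="stable")[:k_eff]
                keep = order[row[order] > 0]
                W[i, keep] = self.similarity_[i, keep]
            self.graph_ = W
        return self

    def transform(self, records=None):
        return self.graph_


def cosine_matrix(X: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarity of feature rows (test oracle helper)."""
    X = np.asarray(X, dtype=float)
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    Xn = X / norms
    return Xn @ Xn.T


ALL_KMERS = {k: ["".join(p) for p in itertools.product("ACGU", repeat=k)] for k in (1, 2)}
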