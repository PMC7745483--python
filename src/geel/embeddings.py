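"""Five graph-embedding methods over the heterogeneous network.

All estimators share the interface ``fit(H)`` -> fitted ``embedding_`` of
shape (n_nodes, n_components), with rows ordered like H (lncRNAs first, then
miRNAs).  Methods:

* :class:`LaplacianEigenmapsEmbedding` — smallest nontrivial generalized
  eigenvectors of (L, D), preserving local neighborhoods.
* :class:`GraRepEmbedding` — truncated SVD of positive log-transformed
  k-step transition matrices (global structural information).
* :class:`HOPEEmbedding` — low-rank factorization of Katz proximity.
* :class:`DeepWalkEmbedding` — skip-gram with negative sampling trained on
  truncated random-walk sentences.
* :class:`GAEEmbedding` — (variational) graph autoencoder: two-layer graph
  convolutional encoder with inner-product decoder.

Spectral methods carry the usual sign/rotation indeterminacy; downstream
code only ever uses Gram/classifier-level information, which is invariant.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator

from .hetnet import HeterogeneousNetwork


def _as_matrix(H) -> np.ndarray:
    if isinstance(H, HeterogeneousNetwork):
        H = H.H
    H = np.asarray(H, dtype=float)
    if H.ndim != 2 or H.shape[0] != H.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(H, H.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if (H < 0).any():
        raise ValueError("adjacency must be nonnegative")
    return H


class GraphEmbedding(BaseEstimator):
    """Base class: common validation and the fitted-attribute contract."""

    method: str = "base"

    def __init__(self, n_components: int = 120):
        self.n_components = n_components

    def _validate(self, H) -> np.ndarray:
        H = _as_matrix(H)
        if self.n_components > H.shape[0]:
            raise ValueError(
                f"n_components={self.n_components} must be <= n_nodes={H.shape[0]}"
            )
        return H

    def _finalize(self, E: np.ndarray) -> "GraphEmbedding":
        if not np.isfinite(E).all():
            raise RuntimeError(f"{self.method}: non-finite entries in embedding")
        self.embedding_ = E
        self.n_nodes_ = E.shape[0]
        return self

    def fit_transform(self, H, y=None) -> np.ndarray:
        self.fit(H)
        return self.embedding_


class LaplacianEigenmapsEmbedding(GraphEmbedding):
    """Spectral embedding from the generalized problem L v = lam D v.

    Columns are the eigenvectors of the theta smallest *nonzero* eigenvalues
    in ascending order; the constant (zero-eigenvalue) vector is excluded.
    Eigenvectors are D-normalized (v' D v = 1), hence D-orthogonal to the
    constant vector.  A disconnected graph contributes one zero eigenvalue
    per component; all are excluded with a warning.
    """

    method = "LE"

    def __init__(self, n_components: int = 120, zero_tol: float = 1e-9):
        super().__init__(n_components)
        self.zero_tol = zero_tol

    def fit(self, H, y=None):
        from scipy.linalg import eigh

        H = self._validate(H)
        deg = H.sum(axis=1)
        if (deg <= 0).any():
            raise ValueError(f"zero-degree nodes {np.where(deg <= 0)[0].tolist()}: Laplacian pencil is singular")
        L = np.diag(deg) - H
        vals, vecs = eigh(L, np.diag(deg))
        scale = max(vals.max(), 1.0)
        nonzero = vals > self.zero_tol * scale
        n_zero = int((~nonzero).sum())
        if n_zero > 1:
            warnings.warn(f"graph has {n_zero} connected components; embedding them jointly")
        if nonzero.sum() < self.n_components:
            raise ValueError(
                f"only {int(nonzero.sum())} nonzero eigenvalues available, need n_components={self.n_components}"
            )
        keep = np.where(nonzero)[0][: self.n_components]
        V = vecs[:, keep]
        # eigh(L, D) already returns v' D v = 1; re-normalize defensively
        dn = np.einsum("ij,i,ij->j", V, deg, V)
        V = V / np.sqrt(dn)
        self.eigenvalues_ = vals[keep]
        return self._finalize(V)


class GraRepEmbedding(GraphEmbedding):
    """Global-structure embedding from k-step transition matrices.

    For each step s = 1..k_step: P = D^-1 H, X_s = max(log(P^s) -
    log(colmean(P^s)) - log(shift), 0); a rank-(theta/k_step) truncated SVD
    of X_s gives the block U sqrt(Sigma); blocks are concatenated.
    """

    method = "GraRep"

    def __init__(self, n_components: int = 120, k_step: int = 1, shift: float = 1.0):
        super().__init__(n_components)
        self.k_step = k_step
        self.shift = shift

    def fit(self, H, y=None):
        H = self._validate(H)
        if not (1 <= self.k_step <= 4):
            raise ValueError("k_step must be in {1, 2, 3, 4}")
        if self.n_components % self.k_step:
            raise ValueError(f"n_components={self.n_components} must be divisible by k_step={self.k_step}")
        deg = H.sum(axis=1)
        if (deg <= 0).any():
            raise ValueError(f"zero-degree nodes {np.where(deg <= 0)[0].tolist()}: transition matrix undefined")
        P = H / deg[:, None]
        dim = self.n_components // self.k_step
        blocks = []
        self.targets_ = []
        self.context_ = []
        Ps = np.eye(H.shape[0])
        for _ in range(self.k_step):
            Ps = Ps @ P
            col_mean = Ps.mean(axis=0)
            with np.errstate(divide="ignore"):
                X = np.log(Ps) - np.log(col_mean)[None, :] - np.log(self.shift)
            X[~np.isfinite(X)] = 0.0
            np.maximum(X, 0.0, out=X)
            U, s, Vt = np.linalg.svd(X, full_matrices=False)
            blocks.append(U[:, :dim] * np.sqrt(s[:dim]))
            self.context_.append(Vt[:dim].T * np.sqrt(s[:dim]))
            self.targets_.append(X)
        return self._finalize(np.hstack(blocks))


class HOPEEmbedding(GraphEmbedding):
    """High-order proximity embedding via Katz-index factorization.

    Katz proximity S = (I - b H)^-1 b H converges iff b < 1/rho(H); the
    default decay is 0.5/rho(H).  A rank-(theta/2) SVD of S yields source
    (U sqrt(Sigma)) and target (V sqrt(Sigma)) embeddings, concatenated.
    """

    method = "HOPE"

    def __init__(self, n_components: int = 120, katz_decay: float | None = None):
        super().__init__(n_components)
        self.katz_decay = katz_decay

    def fit(self, H, y=None):
        H = self._validate(H)
        if self.n_components % 2:
            raise ValueError("n_components must be even (source + target halves)")
        rho = max(float(np.max(np.abs(np.linalg.eigvalsh(H)))), 1e-12)
        decay = 0.5 / rho if self.katz_decay is None else self.katz_decay
        if decay >= 1.0 / rho:
            raise ValueError(
                f"katz_decay={decay} >= 1/spectral_radius={1.0 / rho:.6g}; Katz series diverges"
            )
        self.katz_decay_ = decay
        n = H.shape[0]
        S = np.linalg.solve(np.eye(n) - decay * H, decay * H)
        U, s, Vt = np.linalg.svd(S, full_matrices=False)
        half = self.n_components // 2
        root = np.sqrt(s[:half])
        self.katz_matrix_ = S
        return self._finalize(np.hstack([U[:, :half] * root, Vt[:half].T * root]))


class DeepWalkEmbedding(GraphEmbedding):
    """Skip-gram embeddings of truncated random walks on the weighted graph.

    ``walks_per_vertex`` walks of length ``walk_length`` start from every
    node (start order reshuffled per pass); transition probabilities are the
    degree-normalized edge weights.  The walk corpus trains skip-gram with
    negative sampling (window ``window``, ``n_negative`` noise words drawn
    from the unigram^0.75 distribution).  Isolated nodes walk in place.
    """

    method = "DeepWalk"

    def __init__(
        self,
        n_components: int = 120,
        walk_length: int = 80,
        walks_per_vertex: int = 30,
        window: int = 30,
        n_negative: int = 5,
        epochs: int = 5,
        learning_rate: float = 0.05,
        batch_size: int = 512,
        random_state: int = 0,
    ):
        super().__init__(n_components)
        self.walk_length = walk_length
        self.walks_per_vertex = walks_per_vertex
        self.window = window
        self.n_negative = n_negative
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.random_state = random_state

    # -- corpus ------------------------------------------------------------
    def generate_walks(self, H, rng: np.random.Generator | None = None) -> np.ndarray:
        """Return the walk corpus, shape (n_nodes * walks_per_vertex, walk_length)."""
        H = _as_matrix(H)
        n = H.shape[0]
        rng = rng or np.random.default_rng(self.random_state)
        nbrs, cums = [], []
        for u in range(n):
            idx = np.nonzero(H[u])[0]
            nbrs.append(idx)
            w = H[u, idx]
            cums.append(np.cumsum(w) / w.sum() if idx.size else None)
        walks = np.empty((n * self.walks_per_vertex, self.walk_length), dtype=np.int32)
        row = 0
        for _ in range(self.walks_per_vertex):
            order = rng.permutation(n)
            for start in order:
                cur = start
                walk = walks[row]
                walk[0] = cur
                for step in range(1, self.walk_length):
                    if cums[cur] is None:  # isolated: walk in place
                        walk[step] = cur
                        continue
                    u = rng.random()
                    cur = int(nbrs[cur][np.searchsorted(cums[cur], u)])
                    walk[step] = cur
                row += 1
        return walks

    def _pairs(self, walks: np.ndarray) -> np.ndarray:
        """All (center, context) pairs within the fixed window."""
        chunks = []
        T = walks.shape[1]
        for off in range(1, min(self.window, T - 1) + 1):
            left = walks[:, :-off].ravel()
            right = walks[:, off:].ravel()
            chunks.append(np.column_stack([left, right]))
            chunks.append(np.column_stack([right, left]))
        return np.concatenate(chunks, axis=0)

    def fit(self, H, y=None):
        Hm = self._validate(H)
        n = Hm.shape[0]
        rng = np.random.default_rng(self.random_state)
        walks = self.generate_walks(Hm, rng)
        self.walks_ = walks
        pairs = self._pairs(walks)
        # unigram^0.75 noise distribution over corpus token frequencies
        freq = np.bincount(walks.ravel(), minlength=n).astype(float) ** 0.75
        noise_cdf = np.cumsum(freq / freq.sum())
        dim = self.n_components
        W_in = (rng.random((n, dim)) - 0.5) / dim
        W_out = np.zeros((n, dim))
        n_batches_total = self.epochs * max(1, -(-len(pairs) // self.batch_size))
        batch_no = 0
        for _ in range(self.epochs):
            perm = rng.permutation(len(pairs))
            for lo in range(0, len(perm), self.batch_size):
                # word2vec-style linear decay to 10% of the initial rate
                lr = self.learning_rate * (1.0 - 0.9 * batch_no / n_batches_total)
                batch_no += 1
                sel = perm[lo : lo + self.batch_size]
                c, o = pairs[sel, 0], pairs[sel, 1]
                negs = np.searchsorted(noise_cdf, rng.random((sel.size, self.n_negative))).astype(np.int64)
                vc = W_in[c]
                uo = W_out[o]
                un = W_out[negs]
                g_pos = _sigmoid(np.einsum("bd,bd->b", vc, uo)) - 1.0
                g_neg = _sigmoid(np.einsum("bd,bkd->bk", vc, un))
                grad_vc = g_pos[:, None] * uo + np.einsum("bk,bkd->bd", g_neg, un)
                # a node can occur many times per batch (small vocabulary):
                # average its accumulated gradient so the step size matches
                # per-pair SGD instead of scaling with the occurrence count
                _scatter_mean_update(W_in, c, grad_vc, lr)
                out_idx = np.concatenate([o, negs.ravel()])
                out_grad = np.concatenate(
                    [g_pos[:, None] * vc, (g_neg[:, :, None] * vc[:, None, :]).reshape(-1, dim)]
                )
                _scatter_mean_update(W_out, out_idx, out_grad, lr)
        return self._finalize(W_in)


def _scatter_mean_update(W: np.ndarray, idx: np.ndarray, grads: np.ndarray, lr: float) -> None:
    """W[idx] -= lr * mean of the gradient rows landing on each index."""
    acc = np.zeros_like(W)
    np.add.at(acc, idx, grads)
    counts = np.bincount(idx, minlength=W.shape[0])
    nz = counts > 0
    W[nz] -= lr * acc[nz] / counts[nz, None]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class GAEEmbedding(GraphEmbedding):
    """(Variational) graph autoencoder with inner-product decoder.

    Encoder: H1 = ReLU(A_hat W1), mu = A_hat H1 W_mu (plus a log-std head in
    variational mode), where A_hat is the symmetrically normalized weighted
    adjacency with self-loops and node features are one-hot (identity).
    Decoder: sigmoid(Z Z').  The loss is the positive-reweighted
    cross-entropy over the full adjacency (plus the KL term in variational
    mode), minimized full-batch with Adam.  The returned embedding is the
    latent mean.
    """

    method = "GAE"

    def __init__(
        self,
        n_components: int = 120,
        hidden_size: int = 512,
        variational: bool = True,
        epochs: int = 200,
        learning_rate: float = 0.01,
        random_state: int = 0,
    ):
        super().__init__(n_components)
        self.hidden_size = hidden_size
        self.variational = variational
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.random_state = random_state

    def fit(self, H, y=None):
        H = self._validate(H)
        n = H.shape[0]
        rng = np.random.default_rng(self.random_state)
        A_tilde = H + np.eye(n)
        d_inv_sqrt = 1.0 / np.sqrt(A_tilde.sum(axis=1))
        A_hat = A_tilde * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]
        T = (H > 0).astype(float)
        np.fill_diagonal(T, 1.0)  # self-edges as positive labels
        n_pos = T.sum()
        pos_weight = (n * n - n_pos) / n_pos
        norm = n * n / (2.0 * (n * n - n_pos))

        def glorot(fan_in, fan_out):
            s = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-s, s, size=(fan_in, fan_out))

        beta, dim = self.hidden_size, self.n_components
        params = {"W1": glorot(n, beta), "Wmu": glorot(beta, dim)}
        if self.variational:
            params["Wls"] = glorot(beta, dim)
        adam_m = {k: np.zeros_like(v) for k, v in params.items()}
        adam_v = {k: np.zeros_like(v) for k, v in params.items()}
        b1, b2, eps = 0.9, 0.999, 1e-8

        def forward(noise):
            pre1 = A_hat @ params["W1"]
            H1 = np.maximum(pre1, 0.0)
            AH1 = A_hat @ H1
            mu = AH1 @ params["Wmu"]
            if self.variational:
                logstd = np.clip(AH1 @ params["Wls"], -10, 10)
                Z = mu + noise * np.exp(logstd)
            else:
                logstd, Z = None, mu
            return pre1, H1, AH1, mu, logstd, Z

        def recon_loss(Z):
            logits = Z @ Z.T
            # numerically stable weighted BCE
            log_sig = -np.logaddexp(0.0, -logits)
            log_1msig = -np.logaddexp(0.0, logits)
            ell = -(pos_weight * T * log_sig + (1 - T) * log_1msig)
            return norm * ell.mean(), logits

        self.loss_history_ = []
        for epoch in range(self.epochs):
            noise = rng.standard_normal((n, dim)) if self.variational else None
            pre1, H1, AH1, mu, logstd, Z = forward(noise)
            loss, logits = recon_loss(Z)
            if self.variational:
                kl = -0.5 / n * np.sum(1 + 2 * logstd - mu**2 - np.exp(2 * logstd))
                loss = loss + kl
            if not np.isfinite(loss):
                raise RuntimeError(f"GAE: non-finite loss at epoch {epoch}: {loss}")
            self.loss_history_.append(float(loss))
            # backward
            sig = _sigmoid(logits)
            dlogits = norm / (n * n) * (sig * (1 + (pos_weight - 1) * T) - pos_weight * T)
            dZ = (dlogits + dlogits.T) @ Z
            if self.variational:
                dmu = dZ + mu / n
                dlogstd = dZ * noise * np.exp(logstd) + (np.exp(2 * logstd) - 1) / n
                dWls = AH1.T @ dlogstd
                dAH1 = dmu @ params["Wmu"].T + dlogstd @ params["Wls"].T
            else:
                dmu = dZ
                dAH1 = dmu @ params["Wmu"].T
            dWmu = AH1.T @ dmu
            dH1 = A_hat.T @ dAH1
            dpre1 = dH1 * (pre1 > 0)
            dW1 = A_hat.T @ dpre1
            grads = {"W1": dW1, "Wmu": dWmu}
            if self.variational:
                grads["Wls"] = dWls
            t_step = epoch + 1
            for k in params:
                adam_m[k] = b1 * adam_m[k] + (1 - b1) * grads[k]
                adam_v[k] = b2 * adam_v[k] + (1 - b2) * grads[k] ** 2
                m_hat = adam_m[k] / (1 - b1**t_step)
                v_hat = adam_v[k] / (1 - b2**t_step)
                params[k] -= self.learning_rate * m_hat / (np.sqrt(v_hat) + eps)
        _pre1, _H1, _AH1, mu, _logstd, _Z = forward(np.zeros((n, dim)) if self.variational else None)
        self.params_ = params
        return self._finalize(mu)

    def decode(self, E: np.ndarray | None = None) -> np.ndarray:
        """Edge-probability matrix sigmoid(Z Z') of a fitted model."""
        Z = self.embedding_ if E is None else E
        return _sigmoid(Z @ Z.T)


_METHODS = {
    "LE": LaplacianEigenmapsEmbedding,
    "GraRep": GraRepEmbedding,
    "HOPE": HOPEEmbedding,
    "DeepWalk": DeepWalkEmbedding,
    "GAE": GAEEmbedding,
}

EMBEDDING_METHODS = tuple(_METHODS)


def make_embedder(method: str, **kwargs) -> GraphEmbedding:
    """Factory by method name: LE, GraRep, HOPE, DeepWalk or GAE."""
    try:
        cls = _METHODS[method]
    except KeyError:
        raise ValueError(f"unknown embedding method {method!r}; choose from {sorted(_METHODS)}") from None
    return cls(**kwargs)


def pair_feature(E: np.ndarray, i: int, j: int, r: int) -> np.ndarray:
    """Concatenated pair vector [E[i]; E[r + j]] for lncRNA i, miRNA j."""
    n = E.shape[0]
    t = n - r
    if not (0 <= i < r):
        raise IndexError(f"lncRNA index {i} out of range [0, {r})")
    if not (0 <= j < t):
        raise IndexError(f"miRNA index {j} out of range [0, {t})")
    return np.concatenate([E[i], E[r + j]])


def pair_feature_matrix(E: np.ndarray, pairs: np.ndarray, r: int) -> np.ndarray:
    """Vectorized pair features: rows [E[i]; E[r+j]] for each (i, j) in pairs."""
    pairs = np.asarray(pairs)
    return np.hstack([E[pairs[:, 0]], E[r + pairs[:, 1]]])
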