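"""GEEL-FI: attention-based feature integration.

A deep attention neural network (DANN) fuses several node-embedding views
into one pair feature.  Per view k, per entity kind, a scalar attention
weight a_k (softmax over trainable logits) weighs the view:

    L_i = sum_k softmax(a^l)_k * l_i^k        (lncRNA merge)
    M_j = sum_k softmax(a^m)_k * m_j^k        (miRNA merge)
    F_ij = [L_i ; M_j]

F_ij passes through ReLU fully-connected layers and a sigmoid output; the
mean binary cross-entropy over the training pair grid is minimized by
gradient descent, training the attention logits (and optional per-view
linear projections that reconcile the embedding width with the pair-feature
width) jointly with the layers.  The trained attention then produces pair
features for a Random Forest classifier, which emits the final scores.

Switching ``attention=False`` freezes every view weight at 1 — the plain
unweighted sum — giving the GEEL-F ablation exactly.

All gradients are derived analytically; ``DANN.loss_and_grads`` is written
to be checkable against central finite differences.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier

HIDDEN_PRESETS = {"table": (240, 120), "text": (120, 60)}


def _softmax(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - z.max())
    return e / e.sum()


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def attention_merge(views: list[np.ndarray], logits: np.ndarray, attention: bool = True) -> np.ndarray:
    """Convex (softmax-weighted) combination of equally-shaped views.

    With ``attention=False`` the views are summed with unit weights (the
    GEEL-F ablation).  K = 1 reduces to the single view exactly.
    """
    shapes = {v.shape for v in views}
    if len(shapes) != 1:
        raise ValueError(f"views must share a shape, got {sorted(shapes)}")
    w = _softmax(np.asarray(logits, dtype=float)) if attention else np.ones(len(views))
    if w.size != len(views):
        raise ValueError("one logit per view required")
    out = np.zeros_like(views[0], dtype=float)
    for wk, v in zip(w, views):
        out += wk * v
    return out


class DANN:
    """Deep attention neural network over K embedding views.

    Parameters
    ----------
    view_dims : input width of each view (embedding dimension per method).
    pair_dim : width of the pair feature F_ij (so each merged entity vector
        has pair_dim/2 entries).  When a view's width differs from
        pair_dim/2 a per-view linear projection (trained jointly) maps it
        there; equal widths skip the projection.
    hidden : ReLU layer sizes of the fully-connected trunk.
    attention : trainable softmax attention (True) or frozen unit weights —
        the unweighted sum of views (False, the GEEL-F ablation).
    learning_rate, epochs : plain full-batch gradient descent controls.
    optimizer : "gd" (vanilla, the default) or "adam".
    """

    def __init__(
        self,
        view_dims: list[int],
        pair_dim: int = 160,
        hidden: tuple[int, ...] = HIDDEN_PRESETS["table"],
        attention: bool = True,
        learning_rate: float = 0.01,
        epochs: int = 200,
        optimizer: str = "gd",
        random_state: int = 0,
    ):
        if pair_dim % 2:
            raise ValueError("pair_dim must be even")
        self.view_dims = list(view_dims)
        self.K = len(view_dims)
        self.pair_dim = pair_dim
        self.half = pair_dim // 2
        self.hidden = tuple(hidden)
        self.attention = attention
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.optimizer = optimizer
        self.random_state = random_state
        self.project = any(d != self.half for d in self.view_dims)
        self.params = self._init_params(np.random.default_rng(random_state))
        self.trained_ = False

    def _init_params(self, rng) -> dict[str, np.ndarray]:
        p: dict[str, np.ndarray] = {
            "logits_l": np.zeros(self.K),
            "logits_m": np.zeros(self.K),
        }
        if self.project:
            for k, d in enumerate(self.view_dims):
                p[f"P{k}"] = rng.standard_normal((d, self.half)) * np.sqrt(2.0 / d)
        sizes = (self.pair_dim, *self.hidden, 1)
        for layer, (fan_in, fan_out) in enumerate(zip(sizes[:-1], sizes[1:]), start=1):
            p[f"W{layer}"] = rng.standard_normal((fan_in, fan_out)) * np.sqrt(2.0 / fan_in)
            p[f"b{layer}"] = np.zeros(fan_out)
        return p

    # ------------------------------------------------------------- forward
    def _projected_views(self, views_l, views_m):
        if self.project:
            Vl = [X @ self.params[f"P{k}"] for k, X in enumerate(views_l)]
            Vm = [X @ self.params[f"P{k}"] for k, X in enumerate(views_m)]
        else:
            Vl, Vm = list(views_l), list(views_m)
        return Vl, Vm

    def _weights(self):
        if self.attention:
            return _softmax(self.params["logits_l"]), _softmax(self.params["logits_m"])
        return np.ones(self.K), np.ones(self.K)

    def merge(self, views_l, views_m):
        """Merged entity representations (L: r x half, M: t x half)."""
        Vl, Vm = self._projected_views(views_l, views_m)
        wl, wm = self._weights()
        L = sum(w * V for w, V in zip(wl, Vl))
        M = sum(w * V for w, V in zip(wm, Vm))
        return L, M

    def pair_features(self, views_l, views_m, pairs) -> np.ndarray:
        """F_ij = [L_i ; M_j] for each (i, j) row of ``pairs``."""
        L, M = self.merge(views_l, views_m)
        pairs = np.asarray(pairs)
        return np.hstack([L[pairs[:, 0]], M[pairs[:, 1]]])

    def forward(self, F: np.ndarray) -> np.ndarray:
        """Scores sigmoid(W_out Z_L + b_out) for pair-feature rows F."""
        return _sigmoid(self._forward_cache(F)[-1][0])

    def _forward_cache(self, F):
        acts = [F]
        n_layers = len(self.hidden) + 1
        Z = F
        for layer in range(1, n_layers):
            pre = Z @ self.params[f"W{layer}"] + self.params[f"b{layer}"]
            Z = np.maximum(pre, 0.0)
            acts.append((pre, Z))
        logits = (Z @ self.params[f"W{n_layers}"] + self.params[f"b{n_layers}"]).ravel()
        acts.append((logits,))
        return acts

    # ------------------------------------------------------------ backward
    def loss_and_grads(self, views_l, views_m, pairs, y):
        """Mean BCE over pairs and its analytic gradient w.r.t. every
        trainable parameter (attention logits, projections, layer weights)."""
        pairs = np.asarray(pairs)
        y = np.asarray(y, dtype=float)
        B = len(pairs)
        Vl, Vm = self._projected_views(views_l, views_m)
        wl, wm = self._weights()
        L = sum(w * V for w, V in zip(wl, Vl))
        M = sum(w * V for w, V in zip(wm, Vm))
        FL, FM = L[pairs[:, 0]], M[pairs[:, 1]]
        F = np.hstack([FL, FM])
        acts = self._forward_cache(F)
        logits = acts[-1][0]
        # stable BCE: mean softplus(z) - y z
        loss = float(np.mean(np.logaddexp(0.0, logits) - y * logits))
        grads: dict[str, np.ndarray] = {}
        dlogits = (_sigmoid(logits) - y) / B
        n_layers = len(self.hidden) + 1
        Z_last = acts[-2][1] if n_layers > 1 else F
        grads[f"W{n_layers}"] = Z_last.T @ dlogits[:, None]
        grads[f"b{n_layers}"] = np.array([dlogits.sum()])
        dZ = dlogits[:, None] @ self.params[f"W{n_layers}"].T
        for layer in range(n_layers - 1, 0, -1):
            pre, _ = acts[layer]
            dpre = dZ * (pre > 0)
            Z_prev = acts[layer - 1] if layer == 1 else acts[layer - 1][1]
            grads[f"W{layer}"] = Z_prev.T @ dpre
            grads[f"b{layer}"] = dpre.sum(axis=0)
            dZ = dpre @ self.params[f"W{layer}"].T
        dF = dZ
        dFL, dFM = dF[:, : self.half], dF[:, self.half :]
        dL = np.zeros_like(L)
        dM = np.zeros_like(M)
        np.add.at(dL, pairs[:, 0], dFL)
        np.add.at(dM, pairs[:, 1], dFM)
        # attention: dw_k = <dL, V_k>; softmax jacobian back to logits
        if self.attention:
            dwl = np.array([np.sum(dL * V) for V in Vl])
            dwm = np.array([np.sum(dM * V) for V in Vm])
            grads["logits_l"] = wl * (dwl - np.dot(wl, dwl))
            grads["logits_m"] = wm * (dwm - np.dot(wm, dwm))
        else:
            grads["logits_l"] = np.zeros(self.K)
            grads["logits_m"] = np.zeros(self.K)
        if self.project:
            for k in range(self.K):
                grads[f"P{k}"] = views_l[k].T @ (wl[k] * dL) + views_m[k].T @ (wm[k] * dM)
        return loss, grads

    def fit(self, views_l, views_m, pairs, y):
        """Full-batch gradient descent on the mean BCE (Adam optional)."""
        lr = self.learning_rate
        if self.optimizer == "adam":
            m = {k: np.zeros_like(v) for k, v in self.params.items()}
            v = {k: np.zeros_like(v_) for k, v_ in self.params.items()}
        self.loss_history_ = []
        for epoch in range(self.epochs):
            loss, grads = self.loss_and_grads(views_l, views_m, pairs, y)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"DANN: divergent loss at epoch {epoch}; last finite loss "
                    f"{self.loss_history_[-1] if self.loss_history_ else 'n/a'}"
                )
            self.loss_history_.append(loss)
            for key, g in grads.items():
                if not self.attention and key.startswith("logits"):
                    continue
                if self.optimizer == "adam":
                    t = epoch + 1
                    m[key] = 0.9 * m[key] + 0.1 * g
                    v[key] = 0.999 * v[key] + 0.001 * g**2
                    self.params[key] -= lr * (m[key] / (1 - 0.9**t)) / (np.sqrt(v[key] / (1 - 0.999**t)) + 1e-8)
                else:
                    self.params[key] -= lr * g
        self.trained_ = True
        return self

    @property
    def attention_weights_(self) -> dict[str, np.ndarray]:
        if not self.trained_:
            raise RuntimeError("attention weights requested before training")
        wl, wm = self._weights()
        return {"lncRNA": wl, "miRNA": wm}


class GEELFIClassifier(BaseEstimator, ClassifierMixin):
    """Feature-integration ensemble: DANN fusion + Random Forest.

    Parameters
    ----------
    views : ordered embedding-method names entering the fusion
        (epsilon; default ("GraRep", "LE")).
    pair_dim : pair-feature width theta (default 160).
    hidden_preset : "table" -> layers (240, 120), "text" -> (120, 60); or
        pass ``hidden`` explicitly to override.
    attention : False gives the GEEL-F ablation (unweighted view sum).
    n_estimators : forest size eta (default 2000).

    fit takes the training pairs, their labels and a dict of fitted
    embedding matrices plus the lncRNA count r (to split node rows).
    """

    def __init__(
        self,
        views: tuple[str, ...] = ("GraRep", "LE"),
        pair_dim: int = 160,
        hidden_preset: str = "table",
        hidden: tuple[int, ...] | None = None,
        attention: bool = True,
        n_estimators: int = 2000,
        learning_rate: float = 0.01,
        epochs: int = 200,
        optimizer: str = "gd",
        random_state: int = 0,
    ):
        self.views = tuple(views)
        self.pair_dim = pair_dim
        self.hidden_preset = hidden_preset
        self.hidden = hidden
        self.attention = attention
        self.n_estimators = n_estimators
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.optimizer = optimizer
        self.random_state = random_state

    def _split_views(self, embeddings: dict[str, np.ndarray], r: int):
        views_l, views_m = [], []
        for name in self.views:
            if name not in embeddings:
                raise KeyError(f"embedding view {name!r} missing; have {sorted(embeddings)}")
            E = np.asarray(embeddings[name])
            views_l.append(E[:r])
            views_m.append(E[r:])
        return views_l, views_m

    def fit(self, pairs, y, embeddings: dict[str, np.ndarray], r: int):
        pairs = np.asarray(pairs)
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("training pairs must contain both classes")
        views_l, views_m = self._split_views(embeddings, r)
        hidden = self.hidden if self.hidden is not None else HIDDEN_PRESETS[self.hidden_preset]
        self.dann_ = DANN(
            view_dims=[V.shape[1] for V in views_l],
            pair_dim=self.pair_dim,
            hidden=hidden,
            attention=self.attention,
            learning_rate=self.learning_rate,
            epochs=self.epochs,
            optimizer=self.optimizer,
            random_state=self.random_state,
        )
        self.dann_.fit(views_l, views_m, pairs, y)
        F = self.dann_.pair_features(views_l, views_m, pairs)
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_estimators, random_state=self.random_state, n_jobs=1
        ).fit(F, y)
        self.r_ = r
        self._views_l, self._views_m = views_l, views_m
        self.classes_ = self.forest_.classes_
        return self

    def extract_pair_features(self, pairs) -> np.ndarray:
        if not getattr(self, "dann_", None) or not self.dann_.trained_:
            raise RuntimeError("attention not trained; call fit first")
        return self.dann_.pair_features(self._views_l, self._views_m, pairs)

    def predict_proba(self, pairs) -> np.ndarray:
        return self.forest_.predict_proba(self.extract_pair_features(pairs))

    def decision_scores(self, pairs) -> np.ndarray:
        """Interaction probability per pair (positive-class column)."""
        proba = self.predict_proba(pairs)
        return proba[:, list(self.classes_).index(1)]

    def predict(self, pairs) -> np.ndarray:
        return (self.decision_scores(pairs) >= 0.5).astype(int)

    @property
    def attention_weights_(self):
        return self.dann_.attention_weights_
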