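"""GEEL-PI: prediction-integration ensemble.

One Random-Forest base predictor is trained per embedding method on the
concatenated pair features [l_i ; m_j]; a logistic regression phi (L2
regularized, library defaults) maps the five base scores to the final
interaction probability.

The stacking scores that train phi are produced out-of-fold by an inner
cross-validation within the training fold (in-sample scores would overweight
the most overfit base predictor); the base forests are then refit on the
full training fold for test-time scoring.  ``stacking_protocol="insample"``
switches to plain in-sample scores for comparison.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .embeddings import pair_feature_matrix


def train_base_predictor(E: np.ndarray, pairs, y, r: int, seed: int = 0, n_estimators: int = 100):
    """Fit one Random-Forest base predictor on pair features from a single
    embedding matrix.  Library-default forest settings apart from the seed."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training pairs must contain both classes")
    X = pair_feature_matrix(E, pairs, r)
    return RandomForestClassifier(n_estimators=n_estimators, random_state=seed, n_jobs=1).fit(X, y)


def _positive_proba(clf, X) -> np.ndarray:
    proba = clf.predict_proba(X)
    return proba[:, list(clf.classes_).index(1)]


class GEELPIClassifier(BaseEstimator, ClassifierMixin):
    """Stacked ensemble over per-embedding Random-Forest predictors.

    Parameters
    ----------
    methods : embedding views used as base predictors (default all five).
    n_estimators : trees per base forest (library default 100).
    inner_folds : folds of the inner split producing out-of-fold stacking
        scores.
    stacking_protocol : "oof" (default) or "insample".

    ``fit(pairs, y, embeddings, r)`` expects the training pair index array
    (n x 2 of (lncRNA, miRNA) indices), labels, a dict of fitted embedding
    matrices and the lncRNA count r.
    """

    def __init__(
        self,
        methods: tuple[str, ...] = ("LE", "GraRep", "HOPE", "DeepWalk", "GAE"),
        n_estimators: int = 100,
        inner_folds: int = 5,
        stacking_protocol: str = "oof",
        random_state: int = 0,
    ):
        self.methods = tuple(methods)
        self.n_estimators = n_estimators
        self.inner_folds = inner_folds
        self.stacking_protocol = stacking_protocol
        self.random_state = random_state

    def fit(self, pairs, y, embeddings: dict[str, np.ndarray], r: int):
        pairs = np.asarray(pairs)
        y = np.asarray(y)
        missing = [m for m in self.methods if m not in embeddings]
        if missing:
            raise KeyError(f"missing embeddings for base predictors: {missing}")
        if len(np.unique(y)) < 2:
            raise ValueError("training pairs must contain both classes")
        oof = np.zeros((len(pairs), len(self.methods)))
        if self.stacking_protocol == "oof":
            skf = StratifiedKFold(n_splits=self.inner_folds, shuffle=True, random_state=self.random_state)
            splits = list(skf.split(pairs, y))
            for col, name in enumerate(self.methods):
                X = pair_feature_matrix(np.asarray(embeddings[name]), pairs, r)
                for tr, va in splits:
                    clf = RandomForestClassifier(
                        n_estimators=self.n_estimators, random_state=self.random_state, n_jobs=1
                    ).fit(X[tr], y[tr])
                    oof[va, col] = _positive_proba(clf, X[va])
        elif self.stacking_protocol == "insample":
            for col, name in enumerate(self.methods):
                X = pair_feature_matrix(np.asarray(embeddings[name]), pairs, r)
                clf = RandomForestClassifier(
                    n_estimators=self.n_estimators, random_state=self.random_state, n_jobs=1
                ).fit(X, y)
                oof[:, col] = _positive_proba(clf, X)
        else:
            raise ValueError(f"unknown stacking_protocol {self.stacking_protocol!r}")
        if not np.isfinite(oof).all():
            raise ValueError("non-finite base-predictor scores")
        # phi: logistic regression, library defaults (L2 penalty)
        self.stacking_ = LogisticRegression().fit(oof, y)
        self.base_predictors_ = {
            name: train_base_predictor(
                np.asarray(embeddings[name]), pairs, y, r, seed=self.random_state, n_estimators=self.n_estimators
            )
            for name in self.methods
        }
        self.oof_scores_ = oof
        self.r_ = r
        self._embeddings = {name: np.asarray(embeddings[name]) for name in self.methods}
        self.classes_ = self.stacking_.classes_
        return self

    def base_scores(self, pairs) -> np.ndarray:
        """n_pairs x n_methods matrix of base-predictor probabilities."""
        pairs = np.asarray(pairs)
        cols = []
        for name in self.methods:
            X = pair_feature_matrix(self._embeddings[name], pairs, self.r_)
            cols.append(_positive_proba(self.base_predictors_[name], X))
        return np.column_stack(cols)

    def predict_proba(self, pairs) -> np.ndarray:
        return self.stacking_.predict_proba(self.base_scores(pairs))

    def decision_scores(self, pairs) -> np.ndarray:
        """Interaction probability per pair (positive-class column)."""
        proba = self.predict_proba(pairs)
        return proba[:, list(self.classes_).index(1)]

    def predict(self, pairs) -> np.ndarray:
        return (self.decision_scores(pairs) >= 0.5).astype(int)
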