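"""Fuzzy ARTMAP classifier (simplified / category-prediction form).

Adaptive Resonance Theory classifiers grow their own category layer instead
of fixing a hidden-layer size up front.  Each committed category j holds a
weight vector w_j in [0, 1]^(2M) over the complement-coded input
I = (a, 1 - a) (city-block norm |I| = M exactly, which preserves amplitude
information).  Presentation of an input runs a competition with the choice
function

    T_j = |I ^ w_j| / (alpha + |w_j|)        (^ = componentwise min)

and a resonance test against the vigilance rho:

    |I ^ w_j| / |I| >= rho.

On resonance the winning category learns w <- beta * (I ^ w) + (1-beta) * w;
with fast learning (beta = 1) a single presentation suffices.  Supervision
enters through the map field: each category is tied to one class label.  If
the resonating category predicts the wrong class, match tracking raises the
vigilance just above the current match and the search resumes, eventually
committing a fresh category for the pattern.  With baseline vigilance 0 the
network starts from maximally coarse categories and only refines them when
a prediction error forces it to — which is why it reproduces 100 % of a
consistent training set while keeping the category count small.

This is the standard simplified form for classification: the second ART
module is replaced by the class labels themselves, and with one-hot labels
the map-field vigilance test (overlap >= rho_ab) reduces to exact class
agreement for any rho_ab > 0.5, so the conventional "nearly 1" setting
(0.99) behaves as intended.

The algorithm is fully deterministic for a fixed presentation order; an
optional seeded shuffle is provided because ART learning is order-sensitive.
"""

from __future__ import annotations

import json
import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted

logger = logging.getLogger(__name__)

__all__ = [
    "FuzzyArtmapClassifier",
    "complement_code",
    "choice",
    "match",
    "learn",
    "train",
    "predict",
    "save_model",
    "load_model",
]


def complement_code(a: np.ndarray) -> np.ndarray:
    """Complement coding: a in [0,1]^M -> I = (a, 1-a) with |I| = M."""
    a = np.asarray(a, dtype=float)
    bad = np.flatnonzero((a < 0) | (a > 1))
    if bad.size:
        raise ValueError(
            f"input components outside [0, 1] at positions {bad.tolist()[:5]}"
        )
    return np.concatenate([a, 1.0 - a], axis=-1)


def choice(I: np.ndarray, w: np.ndarray, alpha: float) -> float:
    """Choice function T = |I ^ w| / (alpha + |w|)."""
    return float(np.minimum(I, w).sum() / (alpha + w.sum()))


def match(I: np.ndarray, w: np.ndarray) -> float:
    """Match score |I ^ w| / |I| in [0, 1]."""
    return float(np.minimum(I, w).sum() / I.sum())


def learn(w: np.ndarray, I: np.ndarray, beta: float) -> np.ndarray:
    """Resonance update w_new = beta*(I ^ w) + (1-beta)*w (componentwise <= w)."""
    return beta * np.minimum(I, w) + (1.0 - beta) * w


class FuzzyArtmapClassifier(BaseEstimator, ClassifierMixin):
    """Fuzzy ARTMAP with fast learning and match tracking.

    Parameters
    ----------
    rho_a_baseline : float in [0, 1]
        Baseline vigilance of the category module (0: coarsest categories,
        refined only on prediction error).
    rho_ab : float in (0, 1]
        Map-field vigilance; any value > 0.5 demands exact class agreement
        under one-hot labels.
    alpha : float > 0
        Choice parameter; well below 1 to break ties toward the most
        specific (smallest-|w|) matching category.
    beta : float in (0, 1]
        Learning rate; 1 is fast learning.
    epsilon : float > 0
        Match-tracking increment added to the match of a wrongly-predicting
        category (MT+).
    max_epochs : int
        Upper bound on passes over the training set; training stops early
        once no weight changes and no new categories occur in an epoch.
    shuffle : bool, random_state : int or None
        Optional seeded shuffle of the presentation order (ART learning is
        order-sensitive; default keeps dataset order).

    Attributes
    ----------
    weights_ : (n_categories, 2M) committed category weights.
    category_class_ : (n_categories,) index into ``classes_`` per category.
    classes_ : ordered class labels.
    n_epochs_ : epochs actually run.
    input_dim_ : M, the pre-coding feature dimension.
    """

    def __init__(
        self,
        rho_a_baseline: float = 0.0,
        rho_ab: float = 0.99,
        alpha: float = 0.001,
        beta: float = 1.0,
        epsilon: float = 0.001,
        max_epochs: int = 10,
        shuffle: bool = False,
        random_state: int | None = None,
    ):
        self.rho_a_baseline = rho_a_baseline
        self.rho_ab = rho_ab
        self.alpha = alpha
        self.beta = beta
        self.epsilon = epsilon
        self.max_epochs = max_epochs
        self.shuffle = shuffle
        self.random_state = random_state

    def _validate_params_(self) -> None:
        if not 0.0 <= self.rho_a_baseline <= 1.0:
            raise ValueError("rho_a_baseline must be in [0, 1]")
        if not 0.0 < self.rho_ab <= 1.0:
            raise ValueError("rho_ab must be in (0, 1]")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if not 0.0 < self.beta <= 1.0:
            raise ValueError("beta must be in (0, 1]")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")

    def _coded(self, X) -> np.ndarray:
        if isinstance(X, (pd.DataFrame, pd.Series)):
            X = X.to_numpy()
        X = check_array(np.atleast_2d(np.asarray(X, dtype=float)), dtype=float)
        if np.any(X < 0) or np.any(X > 1):
            raise ValueError(
                "inputs must be normalized to [0, 1] (column-max scaling upstream)"
            )
        return complement_code(X)

    def _present(self, I: np.ndarray, target: int) -> bool:
        """One training presentation; returns True if anything changed."""
        rho = self.rho_a_baseline
        n_cat = len(self._w)
        # the uncommitted node (w = all ones) competes too; it caps how far
        # an existing category box can stretch to absorb a distant pattern
        T_unc = I.sum() / (self.alpha + 2.0 * self.input_dim_)
        if n_cat:
            W = np.asarray(self._w)
            overlap = np.minimum(I[None, :], W).sum(axis=1)
            T = overlap / (self.alpha + W.sum(axis=1))
            m = overlap / I.sum()
        masked = np.full(n_cat, False)
        while True:
            best = -1
            if n_cat:
                avail = ~masked
                if avail.any():
                    idx = np.flatnonzero(avail)
                    best = idx[np.argmax(T[idx])]  # argmax, ties -> lowest index
                    if T[best] < T_unc:  # committed wins ties (lower index)
                        best = -1
            if best < 0:
                # uncommitted node wins (or none left): commit a new category
                self._w.append(I.copy())
                self._cat_class.append(target)
                return True
            if m[best] < rho:
                masked[best] = True
                continue
            # map-field test: one-hot overlap >= rho_ab iff same class
            if self._cat_class[best] == target:
                w_new = learn(np.asarray(self._w[best]), I, self.beta)
                changed = not np.array_equal(w_new, self._w[best])
                self._w[best] = w_new
                return changed
            # match tracking: raise vigilance just above the offending match
            rho = m[best] + self.epsilon
            masked[best] = True

    def fit(self, X, y):
        self._validate_params_()
        coded = self._coded(X)
        y = np.asarray(y)
        if len(y) != coded.shape[0]:
            raise ValueError("X and y length mismatch")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        self.input_dim_ = coded.shape[1] // 2
        self.n_features_in_ = self.input_dim_

        order = np.arange(len(y_idx))
        if self.shuffle:
            order = np.random.default_rng(self.random_state).permutation(order)

        self._w: list[np.ndarray] = []
        self._cat_class: list[int] = []
        for epoch in range(self.max_epochs):
            changed = False
            for i in order:
                if self._present(coded[i], int(y_idx[i])):
                    changed = True
            self.n_epochs_ = epoch + 1
            if not changed:
                break
        self.weights_ = np.vstack(self._w)
        self.category_class_ = np.asarray(self._cat_class, dtype=int)
        logger.debug(
            "fuzzy ARTMAP: %d categories for %d patterns (%d epochs)",
            len(self._w), len(y_idx), self.n_epochs_,
        )
        return self

    def partial_fit(self, X, y, classes=None):
        """Incremental (online) learning: extend an already-trained model.

        The first call behaves like ``fit`` (pass ``classes`` to fix the
        label set up front if later batches may omit some classes).
        """
        if not hasattr(self, "weights_"):
            if classes is not None:
                classes = np.asarray(classes)
                y_arr = np.asarray(y)
                if not np.all(np.isin(y_arr, classes)):
                    raise ValueError("y contains labels outside `classes`")
                self._validate_params_()
                coded = self._coded(X)
                self.classes_ = np.unique(classes)
                self.input_dim_ = coded.shape[1] // 2
                self.n_features_in_ = self.input_dim_
                self._w, self._cat_class = [], []
                idx = np.searchsorted(self.classes_, y_arr)
                for i in range(len(idx)):
                    self._present(coded[i], int(idx[i]))
                self.weights_ = np.vstack(self._w)
                self.category_class_ = np.asarray(self._cat_class, dtype=int)
                self.n_epochs_ = 1
                return self
            return self.fit(X, y)
        coded = self._coded(X)
        y_arr = np.asarray(y)
        if not np.all(np.isin(y_arr, self.classes_)):
            raise ValueError("y contains labels unseen at initial fit")
        idx = np.searchsorted(self.classes_, y_arr)
        for i in range(len(idx)):
            self._present(coded[i], int(idx[i]))
        self.weights_ = np.vstack(self._w)
        self.category_class_ = np.asarray(self._cat_class, dtype=int)
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "weights_")
        if len(self.weights_) == 0:
            raise ValueError("model has no committed categories")
        coded = self._coded(X)
        if coded.shape[1] != 2 * self.input_dim_:
            raise ValueError(
                f"X has {coded.shape[1] // 2} features, model was fit with {self.input_dim_}"
            )
        W = self.weights_
        norms = self.alpha + W.sum(axis=1)
        out = np.empty(coded.shape[0], dtype=int)
        for i, I in enumerate(coded):
            overlap = np.minimum(I[None, :], W).sum(axis=1)
            T = overlap / norms
            if self.rho_a_baseline > 0:
                ok = overlap / I.sum() >= self.rho_a_baseline
                T = np.where(ok, T, -np.inf)
            out[i] = self.category_class_[int(np.argmax(T))]
        return self.classes_[out]

    @property
    def n_categories_(self) -> int:
        check_is_fitted(self, "weights_")
        return len(self.weights_)


# ---------------------------------------------------------------------------
# functional façade and JSON serialization


def train(X, y, **hyperparams) -> FuzzyArtmapClassifier:
    return FuzzyArtmapClassifier(**hyperparams).fit(X, y)


def predict(model: FuzzyArtmapClassifier, X) -> np.ndarray:
    return model.predict(X)


def save_model(model: FuzzyArtmapClassifier, path) -> None:
    check_is_fitted(model, "weights_")
    doc = {
        "hyperparams": model.get_params(),
        "input_dim": int(model.input_dim_),
        "classes": [str(c) for c in model.classes_],
        "category_class": model.category_class_.tolist(),
        "weights": model.weights_.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path) -> FuzzyArtmapClassifier:
    with open(path) as fh:
        doc = json.load(fh)
    model = FuzzyArtmapClassifier(**doc["hyperparams"])
    model.classes_ = np.asarray(doc["classes"])
    model.input_dim_ = int(doc["input_dim"])
    model.n_features_in_ = model.input_dim_
    model.weights_ = np.asarray(doc["weights"], dtype=float)
    model.category_class_ = np.asarray(doc["category_class"], dtype=int)
    model._w = [w for w in model.weights_]
    model._cat_class = model.category_class_.tolist()
    model.n_epochs_ = 0
    return model
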