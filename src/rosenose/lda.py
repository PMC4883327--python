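"""Multiclass linear discriminant analysis from scatter matrices.

The classical Fisher construction: with within-class scatter
Sw = sum_c sum_{i in c} (x_i - mu_c)(x_i - mu_c)^T and between-class scatter
Sb = sum_c n_c (mu_c - mu)(mu_c - mu)^T, the discriminant directions are the
leading eigenvectors of the generalized problem Sb w = l Sw w — the linear
combinations that maximise between-class over within-class variance.  For
C classes at most C - 1 directions carry discriminatory power (two here,
LD1 and LD2, the axes of the usual score plot).

Classification uses the equal-covariance Gaussian rule: directions are
scaled so the projected within-class covariance is the identity, and a row
is assigned to the class whose projected centroid maximises
-(1/2)||z - z_c||^2 + log(prior_c) — the Mahalanobis-with-priors rule.

A ridge term (default 1e-8 * trace(Sw)/p) keeps the eigenproblem defined
when Sw is singular, e.g. with a constant column or p close to n.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.linalg
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted

__all__ = ["ScatterLDA", "fit_lda", "project", "predict_lda"]


class ScatterLDA(BaseEstimator, ClassifierMixin):
    """Linear discriminant classifier built from scatter matrices.

    Parameters
    ----------
    priors : dict, array-like, "empirical" or "equal"
        Class prior probabilities; "empirical" (default) uses training
        frequencies.
    n_components : int or None
        Retained discriminant directions; None keeps min(p, C - 1).
    ridge : float
        Relative ridge added to Sw, as a fraction of trace(Sw)/p.

    Attributes
    ----------
    classes_ : ordered class labels.
    means_ : (C, p) class mean vectors.
    xbar_ : (p,) grand mean (prior-weighted).
    within_scatter_, between_scatter_ : (p, p) scatter matrices.
    scalings_ : (p, r) discriminant directions (columns LD1, LD2, ...),
        scaled so the projected within-class covariance is identity and
        sign-fixed so each column's largest-magnitude loading is positive.
    explained_ratio_ : (r,) share of discriminatory variance per direction.
    priors_ : (C,) class priors.
    """

    def __init__(self, priors="empirical", n_components: int | None = None,
                 ridge: float = 1e-8):
        self.priors = priors
        self.n_components = n_components
        self.ridge = ridge

    def fit(self, X, y):
        X = check_array(X, dtype=float, ensure_min_samples=2)
        y = np.asarray(y)
        if len(y) != X.shape[0]:
            raise ValueError("X and y length mismatch")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        n, p = X.shape
        C = len(self.classes_)
        if C < 2:
            raise ValueError("need at least two classes")
        if n <= C:
            raise ValueError(f"need more rows ({n}) than classes ({C})")
        counts = np.bincount(y_idx, minlength=C)
        small = [str(c) for c, m in zip(self.classes_, counts) if m < 2]
        if small:
            raise ValueError(f"classes with fewer than two rows: {small}")

        if isinstance(self.priors, str) and self.priors == "empirical":
            priors = counts / n
        elif isinstance(self.priors, str) and self.priors == "equal":
            priors = np.full(C, 1.0 / C)
        elif isinstance(self.priors, dict):
            priors = np.array([self.priors[c] for c in self.classes_], dtype=float)
        else:
            priors = np.asarray(self.priors, dtype=float)
        if priors.shape != (C,) or np.any(priors <= 0):
            raise ValueError("priors must be positive, one per class")
        self.priors_ = priors / priors.sum()

        self.means_ = np.vstack([X[y_idx == k].mean(axis=0) for k in range(C)])
        self.xbar_ = self.priors_ @ self.means_

        Sw = np.zeros((p, p))
        for k in range(C):
            Xc = X[y_idx == k] - self.means_[k]
            Sw += Xc.T @ Xc
        Sb = np.zeros((p, p))
        for k in range(C):
            d = (self.means_[k] - self.xbar_)[:, None]
            Sb += counts[k] * (d @ d.T)
        self.within_scatter_ = Sw
        self.between_scatter_ = Sb

        lam = self.ridge * np.trace(Sw) / p
        if lam <= 0:  # Sw identically zero: fall back to a tiny absolute ridge
            lam = self.ridge if self.ridge > 0 else 1e-12
        Sw_reg = Sw + lam * np.eye(p)
        evals, evecs = scipy.linalg.eigh(Sb, Sw_reg)
        order = np.argsort(evals)[::-1]
        r = min(p, C - 1)
        if self.n_components is not None:
            r = min(r, self.n_components)
        evals = np.clip(evals[order][:r], 0.0, None)
        W = evecs[:, order[:r]]
        # eigh(b=Sw_reg) normalises W^T Sw_reg W = I; rescale so projected
        # within-class covariance (Sw/(n-C)) is the identity
        W = W * np.sqrt(n - C)
        # sign convention: largest-|loading| component positive per direction
        for j in range(W.shape[1]):
            i = np.argmax(np.abs(W[:, j]))
            if W[i, j] < 0:
                W[:, j] = -W[:, j]
        self.scalings_ = W
        total = evals.sum()
        self.explained_ratio_ = evals / total if total > 0 else np.full(r, 1.0 / r)
        self.n_features_in_ = p
        return self

    def _check_X(self, X) -> np.ndarray:
        check_is_fitted(self, "scalings_")
        if isinstance(X, (pd.DataFrame, pd.Series)):
            X = X.to_numpy()
        X = check_array(np.atleast_2d(np.asarray(X, dtype=float)), dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, model was fit with {self.n_features_in_}"
            )
        return X

    def transform(self, X) -> np.ndarray:
        """Project rows onto the discriminant axes (LD1, LD2, ...)."""
        X = self._check_X(X)
        return (X - self.xbar_) @ self.scalings_

    def decision_function(self, X) -> np.ndarray:
        """Gaussian equal-covariance log-scores, one column per class."""
        Z = self.transform(X)
        Zc = (self.means_ - self.xbar_) @ self.scalings_
        d2 = ((Z[:, None, :] - Zc[None, :, :]) ** 2).sum(axis=2)
        return -0.5 * d2 + np.log(self.priors_)

    def predict(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        best = scores.max(axis=1, keepdims=True)
        out = np.empty(len(scores), dtype=self.classes_.dtype)
        for i, row in enumerate(scores):
            tied = np.flatnonzero(row == best[i])
            if len(tied) > 1:  # larger prior wins, then lower class index
                tied = tied[self.priors_[tied] == self.priors_[tied].max()]
            out[i] = self.classes_[tied[0]]
        return out

    def score_frame(self, X, y=None, index=None) -> pd.DataFrame:
        """LD1/LD2 coordinates as a frame, ready for score-plot export."""
        Z = self.transform(X)
        cols = {f"LD{j + 1}": Z[:, j] for j in range(Z.shape[1])}
        frame = pd.DataFrame(cols, index=index)
        if y is not None:
            frame["true_class"] = np.asarray(y)
        return frame


def fit_lda(X, y, priors="empirical", **kwargs) -> ScatterLDA:
    return ScatterLDA(priors=priors, **kwargs).fit(X, y)


def project(model: ScatterLDA, X) -> np.ndarray:
    return model.transform(X)


def predict_lda(model: ScatterLDA, X) -> np.ndarray:
    return model.predict(X)
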