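"""Fisher-ratio (intra/inter variance) feature ranking.

Each feature column is scored by

    Vr = external variance / internal variance

where the external variance is the variance of the class centroids and the
internal variance is the unweighted average of the within-class variances.
A high Vr means the classes are far apart relative to the replicate scatter,
i.e. the feature discriminates well.  Features are ordered by descending Vr
and the top-k subset feeds the classifiers.

Both variances use the population convention (divide by the number of
points) by default; Vr is invariant to shifting a column or scaling it by a
positive constant, and the *ranking* is unaffected by the divisor choice
when class counts are equal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .features import FeatureMatrix

__all__ = [
    "RankedFeatures",
    "fisher_ratio",
    "rank_features",
    "select_top_k",
    "FisherRatioSelector",
]


def fisher_ratio(
    values: np.ndarray,
    labels: np.ndarray,
    *,
    ddof_external: int = 0,
    ddof_internal: int = 0,
) -> float:
    """Between-centroid variance over mean within-class variance.

    Returns ``inf`` when the internal variance is exactly 0 but the
    centroids differ, and ``nan`` when both variances vanish (constant
    feature).  ``ddof_*`` switch between population (0) and sample (1)
    variance conventions.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    centroids = []
    within = []
    for c in classes:
        grp = values[labels == c]
        if len(grp) < 2:
            raise ValueError(f"class {c!r} has fewer than two observations")
        centroids.append(grp.mean())
        within.append(grp.var(ddof=ddof_internal))
    external = np.var(centroids, ddof=ddof_external)
    internal = float(np.mean(within))
    if internal == 0.0:
        return np.inf if external > 0 else np.nan
    return float(external / internal)


@dataclass
class RankedFeatures:
    """Vr score per feature plus the descending ordering."""

    vr: dict[str, float]
    order: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.order) + 1),
                "feature_name": self.order,
                "vr": [self.vr[name] for name in self.order],
            }
        )


def rank_features(m: FeatureMatrix, **kwargs) -> RankedFeatures:
    """Rank all columns by descending Vr.

    ``inf`` scores sort first, ``nan`` (constant feature) last; ties break
    by ascending column index, so an all-tie matrix keeps its column order.
    """
    selector = FisherRatioSelector(**kwargs).fit(m.X, m.y)
    vr = dict(zip(m.feature_names, selector.scores_))
    order = [m.feature_names[i] for i in selector.ranking_]
    return RankedFeatures(vr=vr, order=order)


def select_top_k(ranked: RankedFeatures, k: int) -> list[str]:
    """First k feature names of the descending-Vr order."""
    if not 1 <= k <= len(ranked.order):
        raise ValueError(f"k must be in [1, {len(ranked.order)}], got {k}")
    return ranked.order[:k]


class FisherRatioSelector(BaseEstimator, TransformerMixin):
    """Select the k features with the highest Fisher ratio.

    Parameters
    ----------
    k : int or None
        Number of features to keep; None keeps all (ranking only).
    ddof_external, ddof_internal : int
        Variance conventions, population (0, default) or sample (1).

    Attributes
    ----------
    scores_ : ndarray of shape (n_features,)
        Vr per column (may contain inf/nan, see :func:`fisher_ratio`).
    ranking_ : ndarray of shape (n_features,)
        Column indices in descending-score order (inf first, nan last,
        ties by ascending index).
    support_ : boolean mask of the selected columns.
    """

    def __init__(self, k: int | None = None, ddof_external: int = 0, ddof_internal: int = 0):
        self.k = k
        self.ddof_external = ddof_external
        self.ddof_internal = ddof_internal

    def fit(self, X, y):
        X_arr = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X_arr.ndim != 2:
            raise ValueError("X must be 2-D")
        if len(y) != X_arr.shape[0]:
            raise ValueError("X and y length mismatch")
        n_features = X_arr.shape[1]
        if self.k is not None and not 1 <= self.k <= n_features:
            raise ValueError(f"k must be in [1, {n_features}], got {self.k}")
        self.scores_ = np.array(
            [
                fisher_ratio(
                    X_arr[:, j],
                    y,
                    ddof_external=self.ddof_external,
                    ddof_internal=self.ddof_internal,
                )
                for j in range(n_features)
            ]
        )
        # descending sort with inf first and nan last; stable in column index
        sort_key = np.where(np.isnan(self.scores_), -np.inf, self.scores_)
        self.ranking_ = np.argsort(-sort_key, kind="stable")
        k = self.k if self.k is not None else n_features
        self.support_ = np.zeros(n_features, dtype=bool)
        self.support_[self.ranking_[:k]] = True
        self.n_features_in_ = n_features
        if hasattr(X, "columns"):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self

    def transform(self, X):
        check_is_fitted(self, "support_")
        if isinstance(X, pd.DataFrame):
            keep = [i for i in self.ranking_ if self.support_[i]]
            return X.iloc[:, keep]
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, selector was fit with {self.n_features_in_}"
            )
        keep = [i for i in self.ranking_ if self.support_[i]]
        return X[:, keep]
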