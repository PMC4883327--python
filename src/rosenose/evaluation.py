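"""Leave-one-out evaluation of the e-nose classifiers.

LOOCV runs one fold per measurement: the classifier trains on the other
n - 1 rows and predicts the held-out one; predictions accumulate into a
3 x 3 confusion matrix (rows = true class, columns = predicted) and a
success rate 100 * trace / n.

``run_experiment`` reproduces the full study grid: for each subset size k
(default 10, 20, 30, 49 features by descending Fisher ratio) and each
classifier (Fuzzy ARTMAP, LDA), one confusion matrix and success rate.

Two leakage regimes are supported.  The default mirrors the original
protocol — column-max normalisation and the feature ranking are computed
once on the full matrix before cross-validation (slightly optimistic, as
every fold has seen the held-out row's scale).  ``fold_safe=True`` instead
refits the scaler and ranking inside each training fold.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone

from .artmap import FuzzyArtmapClassifier
from .features import ColumnMaxScaler, FeatureMatrix
from .lda import ScatterLDA
from .ranking import FisherRatioSelector

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionMatrix",
    "ExperimentReport",
    "default_classifiers",
    "loocv",
    "success_rate",
    "run_experiment",
    "render_report",
]

DEFAULT_KS = (10, 20, 30, 49)


@dataclass
class ConfusionMatrix:
    """Rows = true class, columns = predicted class."""

    classes: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        C = len(self.classes)
        if self.counts.shape != (C, C):
            raise ValueError(f"counts must be {C}x{C}")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes, columns=self.classes)


def success_rate(cm: ConfusionMatrix) -> float:
    """Percent of correctly classified measurements, full precision."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * float(np.trace(cm.counts)) / cm.total


def default_classifiers() -> dict[str, object]:
    """The two study classifiers with their published hyperparameters."""
    return {
        "fuzzy_artmap": FuzzyArtmapClassifier(
            rho_a_baseline=0.0, rho_ab=0.99, alpha=0.001, beta=1.0
        ),
        "lda": ScatterLDA(),
    }


def loocv(
    X,
    y,
    classifier,
    feature_subset: list[str] | None = None,
    classes: tuple[str, ...] | None = None,
) -> ConfusionMatrix:
    """Leave-one-out cross-validation of one classifier.

    ``X`` is a (possibly normalised) feature DataFrame or array; an optional
    ``feature_subset`` restricts to named columns.  Folds run in row order.
    A fold whose training half misses a class is still executed (logged);
    the classifier simply cannot predict that class in that fold.
    """
    if isinstance(X, FeatureMatrix):
        if y is None:
            y = X.y
        X = X.X
    y = np.asarray(y)
    if feature_subset is not None:
        if len(feature_subset) == 0:
            raise ValueError("feature subset must be non-empty")
        X = X[list(feature_subset)]
    X_arr = np.asarray(X, dtype=float)
    n = len(X_arr)
    all_classes = tuple(classes) if classes is not None else tuple(np.unique(y))
    if n < len(all_classes) + 1:
        raise ValueError("need at least one more row than classes")
    idx = {c: i for i, c in enumerate(all_classes)}
    counts = np.zeros((len(all_classes), len(all_classes)), dtype=int)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        y_train = y[mask]
        if len(np.unique(y_train)) < len(all_classes):
            logger.warning("fold %d: training set misses a class", i)
        model = clone(classifier).fit(X_arr[mask], y_train)
        pred = model.predict(X_arr[i : i + 1])[0]
        counts[idx[y[i]], idx[pred]] += 1
        mask[i] = True
    return ConfusionMatrix(classes=all_classes, counts=counts)


def _fold_safe_loocv(
    raw: FeatureMatrix, classifier, k: int, classes: tuple[str, ...]
) -> ConfusionMatrix:
    """LOOCV with scaler and ranking refit inside every training fold."""
    y = np.asarray(raw.y)
    X = raw.X
    n = len(X)
    idx = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        X_tr, y_tr = X.iloc[mask.nonzero()[0]], y[mask]
        scaler = ColumnMaxScaler().fit(X_tr)
        selector = FisherRatioSelector(k=k).fit(scaler.transform(X_tr), y_tr)
        Z_tr = selector.transform(np.asarray(scaler.transform(X_tr)))
        model = clone(classifier).fit(np.clip(Z_tr, 0.0, 1.0), y_tr)
        Z_te = selector.transform(np.asarray(scaler.transform(X.iloc[[i]])))
        pred = model.predict(np.clip(Z_te, 0.0, 1.0))[0]
        counts[idx[y[i]], idx[pred]] += 1
        mask[i] = True
    return ConfusionMatrix(classes=classes, counts=counts)


@dataclass
class ExperimentReport:
    """Grid of (classifier, k) confusion matrices and success rates."""

    cells: dict[tuple[str, int], ConfusionMatrix]
    rates: dict[tuple[str, int], float]
    ranking: list[str]
    metadata: dict = field(default_factory=dict)

    def to_json(self) -> str:
        doc = {
            "metadata": self.metadata,
            "ranking": self.ranking,
            "cells": [
                {
                    "classifier": name,
                    "k": k,
                    "classes": list(cm.classes),
                    "confusion": cm.counts.tolist(),
                    "success_rate": self.rates[(name, k)],
                }
                for (name, k), cm in self.cells.items()
            ],
        }
        return json.dumps(doc, indent=2, sort_keys=True)


def run_experiment(
    features: FeatureMatrix,
    ks: tuple[int, ...] = DEFAULT_KS,
    classifiers: dict[str, object] | None = None,
    fold_safe: bool = False,
    metadata: dict | None = None,
) -> ExperimentReport:
    """Full grid: LOOCV of every classifier at every subset size.

    By default normalisation and the Fisher ranking are computed once on
    the full matrix (the original protocol); ``fold_safe`` recomputes both
    inside each fold.
    """
    classifiers = classifiers if classifiers is not None else default_classifiers()
    classes = tuple(np.unique(features.y))
    scaler = ColumnMaxScaler().fit(features.X)
    X_norm = scaler.transform(features.X)
    selector = FisherRatioSelector().fit(X_norm, features.y)
    ranking = [features.feature_names[i] for i in selector.ranking_]

    cells: dict[tuple[str, int], ConfusionMatrix] = {}
    rates: dict[tuple[str, int], float] = {}
    for k in ks:
        if not 1 <= k <= len(ranking):
            raise ValueError(f"subset size {k} out of range")
        subset = ranking[:k]
        for name, clf in classifiers.items():
            logger.info("LOOCV: %s with %d features", name, k)
            if fold_safe:
                cm = _fold_safe_loocv(features, clf, k, classes)
            else:
                cm = loocv(X_norm, features.y, clf, feature_subset=subset,
                           classes=classes)
            cells[(name, k)] = cm
            rates[(name, k)] = success_rate(cm)

    meta = dict(metadata or {})
    meta.setdefault("n_measurements", len(features.X))
    meta.setdefault("fold_safe", fold_safe)
    meta.setdefault("ks", list(ks))
    meta.setdefault(
        "config_hash",
        hashlib.sha256(
            pd.util.hash_pandas_object(features.X).values.tobytes()
        ).hexdigest()[:16],
    )
    return ExperimentReport(cells=cells, rates=rates, ranking=ranking, metadata=meta)


def render_report(report: ExperimentReport) -> str:
    """Text table of the grid: per (k, classifier) the confusion matrix and
    the integer-rounded success rate (full precision lives in the JSON)."""
    lines = []
    ks = sorted({k for (_, k) in report.cells})
    names = list(dict.fromkeys(name for (name, _) in report.cells))
    for k in ks:
        lines.append(f"== {k} features ==")
        for name in names:
            cm = report.cells[(name, k)]
            rate = report.rates[(name, k)]
            lines.append(f"{name}: success rate {round(rate)}% ({rate:.2f}%)")
            frame = cm.to_frame()
            lines.append(frame.to_string())
        lines.append("")
    return "\n".join(lines)
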