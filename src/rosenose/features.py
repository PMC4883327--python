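"""Transient-curve feature extraction for a 7-sensor MOS e-nose.

A measurement cycle has three phases: baseline in clean air (60 s), sample
headspace injection (200 s) and purge/recovery (500 s).  A reducing analyte
lowers a MOS sensor's resistance from its baseline value Ri to an injection
plateau Rf; conductance is the reciprocal (Gi = 1/Ri, Gf = 1/Rf).  Seven
scalar features summarise each sensor curve:

====  =======================  ==========================================
f1    Ri / Rf                  resistance ratio
f2    Ri - Rf                  resistance drop (Ohm)
f3    (Ri - Rf) / Ri           fractional resistance change
f4    Gf - Gi                  conductance rise (S)
f5    (Gf - Gi) / Gi           fractional conductance change
f6    Ti                       rise time: injection start to 90 % of dR
f7    Tr                       recovery time: purge start to 90 % return
====  =======================  ==========================================

With seven sensors this yields a 49-column feature matrix (columns named
``S{i}f{j}``), which is then scaled column-wise to [0, 1] by dividing each
column by its maximum — the scaling a Fuzzy ARTMAP input layer requires.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

logger = logging.getLogger(__name__)

__all__ = [
    "PhaseSchedule",
    "SensorTransient",
    "Measurement",
    "FeatureMatrix",
    "FEATURE_SHORT_NAMES",
    "segment_phases",
    "extract_features",
    "build_feature_matrix",
    "normalize_columns",
    "ColumnMaxScaler",
    "feature_names",
]

FEATURE_SHORT_NAMES = ("f1", "f2", "f3", "f4", "f5", "f6", "f7")


@dataclass(frozen=True)
class PhaseSchedule:
    """Timing of the three-phase measurement cycle, in seconds."""

    baseline_s: float = 60.0
    injection_s: float = 200.0
    recovery_s: float = 500.0
    sample_period_s: float = 1.0

    def __post_init__(self) -> None:
        for name in ("baseline_s", "injection_s", "recovery_s", "sample_period_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def total_s(self) -> float:
        return self.baseline_s + self.injection_s + self.recovery_s

    @property
    def injection_start_s(self) -> float:
        return self.baseline_s

    @property
    def recovery_start_s(self) -> float:
        return self.baseline_s + self.injection_s

    def times(self) -> np.ndarray:
        """Sample instants [0, total) at the configured period."""
        n = int(round(self.total_s / self.sample_period_s))
        return np.arange(n) * self.sample_period_s


@dataclass
class SensorTransient:
    """One sensor's resistance time series over a full cycle."""

    sensor_id: str
    t: np.ndarray
    R: np.ndarray
    schedule: PhaseSchedule = field(default_factory=PhaseSchedule)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        if self.t.shape != self.R.shape or self.t.ndim != 1:
            raise ValueError("t and R must be 1-D arrays of equal length")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("t must be strictly increasing")
        if np.any(self.R <= 0):
            raise ValueError("all resistances must be positive")


@dataclass
class Measurement:
    """One e-nose measurement: one transient per sensor."""

    measurement_id: str
    genotype: str
    transients: dict[str, SensorTransient]


@dataclass
class FeatureMatrix:
    """n x p feature table with aligned quality labels."""

    X: pd.DataFrame
    y: pd.Series

    def __post_init__(self) -> None:
        if len(self.X) != len(self.y):
            raise ValueError("X and y must have the same number of rows")
        if self.X.isna().any().any():
            raise ValueError("feature matrix contains missing cells")

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)


def feature_names(n_sensors: int = 7) -> list[str]:
    """Column order of the feature matrix: S1f1..S1f7, S2f1..S{n}f7."""
    return [f"S{i}{f}" for i in range(1, n_sensors + 1) for f in FEATURE_SHORT_NAMES]


def segment_phases(tr: SensorTransient) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split sample indices into (baseline, injection, recovery) ranges.

    Boundaries are half-open on the right at the injection and recovery
    start times.  Raises if the series does not span all three phases.
    """
    s = tr.schedule
    t = tr.t
    baseline = np.flatnonzero(t < s.injection_start_s)
    injection = np.flatnonzero((t >= s.injection_start_s) & (t < s.recovery_start_s))
    recovery = np.flatnonzero((t >= s.recovery_start_s) & (t < s.total_s))
    if len(baseline) == 0 or len(injection) == 0 or len(recovery) == 0:
        raise ValueError(
            f"{tr.sensor_id}: time series (t in [{t[0]:g}, {t[-1]:g}] s) does not "
            f"span the {s.total_s:g} s schedule"
        )
    return baseline, injection, recovery


def _interp_crossing(t: np.ndarray, x: np.ndarray, level: float, falling: bool) -> float | None:
    """First time x crosses `level`, linearly interpolated between samples."""
    hit = x <= level if falling else x >= level
    idx = np.flatnonzero(hit)
    if len(idx) == 0:
        return None
    k = idx[0]
    if k == 0:
        return float(t[0])
    x0, x1 = x[k - 1], x[k]
    if x1 == x0:
        return float(t[k])
    frac = (level - x0) / (x1 - x0)
    return float(t[k - 1] + frac * (t[k] - t[k - 1]))


def extract_features(
    tr: SensorTransient,
    baseline_window_s: float = 30.0,
    plateau_window_s: float = 20.0,
) -> dict[str, float]:
    """Extract f1..f7 from one transient.

    Ri is the mean resistance over the last ``baseline_window_s`` of the
    baseline phase (robust to settling); Rf the mean over the last
    ``plateau_window_s`` of the injection phase (the plateau).  Rise and
    recovery times use linearly interpolated 90 %-of-dR crossings; a
    threshold never crossed yields the phase duration with a warning.
    """
    s = tr.schedule
    baseline, injection, recovery = segment_phases(tr)
    t, R = tr.t, tr.R

    bl_t = t[baseline]
    bl_mask = bl_t >= s.injection_start_s - baseline_window_s
    Ri = float(R[baseline][bl_mask].mean())

    inj_t = t[injection]
    pl_mask = inj_t >= s.recovery_start_s - plateau_window_s
    Rf = float(R[injection][pl_mask].mean())

    if Ri <= 0 or Rf <= 0:
        raise ValueError(f"{tr.sensor_id}: nonpositive Ri or Rf")
    Gi, Gf = 1.0 / Ri, 1.0 / Rf
    dR = Ri - Rf

    # rise time: first crossing of Ri - 0.9*dR within the injection phase
    level_rise = Ri - 0.9 * dR
    t_rise = _interp_crossing(inj_t, R[injection], level_rise, falling=dR > 0)
    if t_rise is None:
        logger.warning(
            "%s: 90%% response level never reached; using injection duration",
            tr.sensor_id,
        )
        f6 = s.injection_s
    else:
        f6 = t_rise - s.injection_start_s

    # recovery time: first return to Rf + 0.9*dR within the recovery phase
    level_rec = Rf + 0.9 * dR
    t_rec = _interp_crossing(t[recovery], R[recovery], level_rec, falling=dR < 0)
    if t_rec is None:
        logger.warning(
            "%s: 90%% recovery level never reached; using recovery duration",
            tr.sensor_id,
        )
        f7 = s.recovery_s
    else:
        f7 = t_rec - s.recovery_start_s

    return {
        "f1": Ri / Rf,
        "f2": dR,
        "f3": dR / Ri,
        "f4": Gf - Gi,
        "f5": (Gf - Gi) / Gi,
        "f6": f6,
        "f7": f7,
    }


def build_feature_matrix(
    measurements: list[Measurement],
    labels: dict[str, str] | list[str] | None = None,
    n_sensors: int = 7,
    **extract_kwargs,
) -> FeatureMatrix:
    """Assemble the n x (7*n_sensors) feature matrix S1f1..S{n}f7.

    `labels` maps genotype (or measurement id) to quality class, or is a
    list aligned with `measurements`.  Every measurement must provide all
    sensors; ids must be unique.
    """
    ids = [m.measurement_id for m in measurements]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate measurement ids")
    expected = [f"S{i}" for i in range(1, n_sensors + 1)]
    rows = []
    for m in measurements:
        missing = [sid for sid in expected if sid not in m.transients]
        if missing:
            raise ValueError(
                f"measurement {m.measurement_id}: missing sensors {missing}"
            )
        row = {}
        for sid in expected:
            feats = extract_features(m.transients[sid], **extract_kwargs)
            for fname, val in feats.items():
                row[f"{sid}{fname}"] = val
        rows.append(row)
    X = pd.DataFrame(rows, index=ids, columns=feature_names(n_sensors))

    if labels is None:
        y = pd.Series(["?"] * len(ids), index=ids, name="class")
    elif isinstance(labels, dict):
        y = pd.Series(
            [labels.get(m.measurement_id, labels.get(m.genotype)) for m in measurements],
            index=ids,
            name="class",
        )
        if y.isna().any():
            raise ValueError("labels missing for some measurements")
    else:
        if len(labels) != len(measurements):
            raise ValueError("label list length mismatch")
        y = pd.Series(list(labels), index=ids, name="class")
    return FeatureMatrix(X=X, y=y)


class ColumnMaxScaler(BaseEstimator, TransformerMixin):
    """Scale every column into [0, 1] by dividing by its column maximum.

    This is the normalisation an ARTMAP input layer needs.  An all-zero
    column is left untouched (scale 1).  If any column contains negative
    values, divide-by-max could not keep the [0, 1] contract, so the
    scaler falls back to min-max scaling for those columns and warns.

    Attributes
    ----------
    scale_ : ndarray of shape (n_features,)
        Per-column divisor (the column max, or max-min for fallback columns).
    min_ : ndarray of shape (n_features,)
        Per-column offset (0 except for min-max fallback columns).
    """

    def fit(self, X, y=None):
        X = check_array(X, ensure_2d=True, dtype=float)
        col_min = X.min(axis=0)
        col_max = X.max(axis=0)
        self.min_ = np.zeros(X.shape[1])
        self.scale_ = col_max.copy()
        neg = col_min < 0
        if np.any(neg):
            warnings.warn(
                f"{int(neg.sum())} column(s) contain negative values; "
                "falling back to min-max scaling for those columns",
                UserWarning,
                stacklevel=2,
            )
            self.min_[neg] = col_min[neg]
            self.scale_[neg] = col_max[neg] - col_min[neg]
        self.scale_[self.scale_ == 0] = 1.0  # constant/zero columns untouched
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "scale_")
        index = columns = None
        if isinstance(X, pd.DataFrame):
            index, columns = X.index, X.columns
        X = check_array(X, ensure_2d=True, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, scaler was fit with {self.n_features_in_}"
            )
        out = (X - self.min_) / self.scale_
        if columns is not None:
            return pd.DataFrame(out, index=index, columns=columns)
        return out


def normalize_columns(m: FeatureMatrix) -> tuple[FeatureMatrix, ColumnMaxScaler]:
    """Column-max scale a feature matrix; returns (scaled matrix, scaler)."""
    scaler = ColumnMaxScaler().fit(m.X)
    return FeatureMatrix(X=scaler.transform(m.X), y=m.y), scaler
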