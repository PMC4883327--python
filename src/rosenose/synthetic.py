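"""Synthetic e-nose measurement generator.

The raw sensor recordings behind the rose-oil study are not deposited
anywhere, so this module generates datasets with the statistical structure
the downstream analysis assumes: per-genotype GC-MS composition tables whose
six-constituent totals fall in prescribed class ranges, and 7-sensor MOS
resistance transients whose response depth depends on the sample.

Kinetics are first-order (the standard MOS approximation): during injection
the resistance relaxes exponentially from the baseline Ri toward the plateau
Rf = Ri * (1 - d) with time constant ``tau_rise``; during recovery it relaxes
back toward Ri with ``tau_recovery``.  The response depth d in (0, 1) of a
sensor to a sample is ``base + loadings . aroma``, where ``aroma`` is a
two-factor coordinate of the genotype (think of the two factors as latent
alcohol/terpenoid axes the MOS array senses with overlapping selectivity).

The default genotype coordinates deliberately interleave the three quality
classes in factor space — class clusters are tight but class means are close
to collinear and clusters of different classes sit adjacent — because real
MOS fingerprints are nonlinear in composition and a linear decision rule
should not get the classes for free.  Noise is multiplicative log-normal on
every resistance sample plus a per-measurement relative jitter on the depth.

Randomness derives from one root seed; each measurement draws from its own
``default_rng([seed, index])`` substream, so any subset regenerates
identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .features import Measurement, PhaseSchedule, SensorTransient
from .gcms import (
    QUALITY_CLASSES,
    ConstituentProfile,
    KeyConstituentSet,
    label_dataset,
    load_reference_profiles,
)

__all__ = [
    "SensorSpec",
    "GeneratorConfig",
    "default_config",
    "generate_constituent_table",
    "generate_transient",
    "generate_dataset",
    "write_measurements_csv",
    "read_measurements_csv",
    "write_labels_csv",
    "write_constituent_csv",
    "config_from_yaml",
    "config_to_yaml",
]


@dataclass(frozen=True)
class SensorSpec:
    """One MOS sensor: baseline resistance and aroma-factor sensitivity."""

    sensor_id: str
    name: str
    baseline_ohm: float
    base_depth: float
    loadings: tuple[float, float]

    def __post_init__(self) -> None:
        if self.baseline_ohm <= 0:
            raise ValueError(f"{self.sensor_id}: baseline resistance must be > 0")

    def class_depth(self, quality_class: str, coords: dict[str, tuple[float, float]]) -> float:
        a, b = coords[quality_class]
        return self.base_depth + self.loadings[0] * a + self.loadings[1] * b

    def depth_at(self, aroma: tuple[float, float]) -> float:
        return self.base_depth + self.loadings[0] * aroma[0] + self.loadings[1] * aroma[1]


# Nominal sensor array: ids/targets mirror a TGS/SP MOS line-up; baseline
# resistances and loadings are generator choices.
_DEFAULT_SENSORS = (
    SensorSpec("S1", "organic solvent vapours", 30_000.0, 0.05, (0.75, 0.10)),
    SensorSpec("S2", "methane", 50_000.0, 0.05, (0.10, 0.10)),
    SensorSpec("S3", "LP gas", 20_000.0, 0.05, (0.60, 0.25)),
    SensorSpec("S4", "alcohol", 15_000.0, 0.05, (0.40, 0.40)),
    SensorSpec("S5", "ammonia", 80_000.0, 0.05, (0.08, 0.15)),
    SensorSpec("S6", "LP gas", 10_000.0, 0.05, (0.25, 0.60)),
    SensorSpec("S7", "organic solvent vapours", 25_000.0, 0.05, (0.10, 0.75)),
)

# Fixed aroma-factor coordinates of the ten default genotypes (class layout
# 4/3/3), a "cross" geometry: C1 genotypes along the main diagonal, C2 on a
# horizontal line, C3 on a vertical line, each straddling the C1 band.  Every
# class pair interleaves along every projection direction, so no linear rule
# separates the classes; at the same time every genotype cluster stays
# outside the box spanned by any OTHER class's clusters along at least one
# sensor loading direction — the condition under which an adaptive-resonance
# category box cannot engulf a foreign cluster.  C2 and C3 mirror each other
# under factor swap, so A-heavy and B-heavy sensors are equally informative.
_DEFAULT_COORDS = {
    "g1": (0.24, 0.24),
    "g2": (0.33, 0.33),
    "g3": (0.57, 0.57),
    "g4": (0.66, 0.66),
    "g5": (0.06, 0.45),
    "g6": (0.14, 0.45),
    "g7": (0.86, 0.45),
    "g8": (0.45, 0.06),
    "g9": (0.45, 0.14),
    "g10": (0.45, 0.86),
}

_DEFAULT_CLASSES = ("C1",) * 4 + ("C2",) * 3 + ("C3",) * 3

#: Six-constituent total ranges per class, aligned with the 10 % / 50 % rule.
DEFAULT_CLASS_SPEC = {"C1": (2.0, 9.0), "C2": (12.0, 45.0), "C3": (52.0, 80.0)}

# Nominal class-centroid coordinates used when a transient is generated from
# a bare class label (no genotype context): a simplified one-cluster-per-class
# world in which every positive-loading sensor has a monotone class effect.
_CLASS_CENTERS = {"C1": (0.20, 0.20), "C2": (0.45, 0.45), "C3": (0.70, 0.70)}


@dataclass
class GeneratorConfig:
    """Full description of one synthetic e-nose experiment."""

    n_genotypes: int = 10
    replicates_per_genotype: int = 15
    sensors: tuple[SensorSpec, ...] = _DEFAULT_SENSORS
    schedule: PhaseSchedule = field(default_factory=PhaseSchedule)
    noise_cv: float = 0.02
    depth_jitter_cv: float = 0.05
    tau_rise: float = 20.0
    tau_recovery: float = 60.0
    rng_seed: int = 0
    genotype_classes: tuple[str, ...] = _DEFAULT_CLASSES
    genotype_coords: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_COORDS)
    )
    class_spec: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_SPEC)
    )
    use_reference_profiles: bool = False

    def __post_init__(self) -> None:
        if self.replicates_per_genotype < 1:
            raise ValueError("replicates_per_genotype must be >= 1")
        if self.noise_cv < 0 or self.depth_jitter_cv < 0:
            raise ValueError("noise coefficients must be >= 0")
        if self.tau_rise <= 0 or self.tau_recovery <= 0:
            raise ValueError("time constants must be > 0")
        if len(self.genotype_classes) != self.n_genotypes:
            raise ValueError("genotype_classes must have one entry per genotype")
        for c in self.genotype_classes:
            if c not in QUALITY_CLASSES:
                raise ValueError(f"unknown quality class {c!r}")
        for cls, (lo, hi) in self.class_spec.items():
            if not (0 <= lo < hi):
                raise ValueError(f"class_spec[{cls}]: invalid range ({lo}, {hi})")

    @property
    def genotype_ids(self) -> list[str]:
        return [f"g{i}" for i in range(1, self.n_genotypes + 1)]


def default_config(**overrides) -> GeneratorConfig:
    """The stated default world: 10 genotypes x 15 replicates, 7 sensors."""
    return replace(GeneratorConfig(), **overrides) if overrides else GeneratorConfig()


def _genotype_coords(config: GeneratorConfig) -> dict[str, tuple[float, float]]:
    coords = dict(config.genotype_coords)
    offsets = [(0.0, 0.0), (-0.13, 0.19), (0.19, -0.13), (0.07, 0.07)]
    counters: dict[str, int] = {}
    for gid, cls in zip(config.genotype_ids, config.genotype_classes):
        if gid not in coords:
            k = counters.get(cls, 0)
            counters[cls] = k + 1
            cx, cy = _CLASS_CENTERS[cls]
            ox, oy = offsets[k % len(offsets)]
            coords[gid] = (cx + ox, cy + oy)
    return coords


def generate_constituent_table(
    config: GeneratorConfig,
    class_spec: dict[str, tuple[float, float]] | None = None,
    keys: KeyConstituentSet | None = None,
) -> list[ConstituentProfile]:
    """Draw one GC-MS composition table consistent with the class layout.

    Each genotype's six-constituent total is uniform in its class range and
    split across the six key constituents by a Dirichlet draw weighted
    toward citronellol and geraniol (the dominant rose volatiles).  With
    ``use_reference_profiles`` set, the packaged ten-genotype reference
    table is returned verbatim and no random numbers are consumed.
    """
    if config.use_reference_profiles:
        return load_reference_profiles()
    class_spec = class_spec or config.class_spec
    keys = keys or KeyConstituentSet()
    for cls in set(config.genotype_classes):
        if cls not in class_spec:
            raise ValueError(f"class_spec missing range for {cls}")
        lo, hi = class_spec[cls]
        if hi <= lo or lo < 0:
            raise ValueError(f"class_spec[{cls}]: infeasible range ({lo}, {hi})")
    rng = np.random.default_rng([config.rng_seed, 10_001])
    alpha = np.array([1.0, 1.0, 6.0, 2.0, 5.0, 1.0])  # weight the dominant volatiles
    profiles = []
    for gid, cls in zip(config.genotype_ids, config.genotype_classes):
        lo, hi = class_spec[cls]
        total = rng.uniform(lo, hi)
        shares = rng.dirichlet(alpha)
        percents = dict(zip(keys.names, (total * shares).round(4)))
        profiles.append(ConstituentProfile(genotype_id=gid, percents=percents))
    return profiles


def _closed_form_curve(
    t: np.ndarray,
    schedule: PhaseSchedule,
    Ri: float,
    depth: float,
    tau_rise: float,
    tau_recovery: float,
) -> np.ndarray:
    """Noiseless piecewise-exponential MOS response."""
    Rf = Ri * (1.0 - depth)
    t_inj = schedule.injection_start_s
    t_rec = schedule.recovery_start_s
    R = np.full_like(t, Ri, dtype=float)
    inj = (t >= t_inj) & (t < t_rec)
    R[inj] = Rf + (Ri - Rf) * np.exp(-(t[inj] - t_inj) / tau_rise)
    R_at_purge = Rf + (Ri - Rf) * np.exp(-(t_rec - t_inj) / tau_rise)
    rec = t >= t_rec
    R[rec] = Ri + (R_at_purge - Ri) * np.exp(-(t[rec] - t_rec) / tau_recovery)
    return R


def generate_transient(
    genotype_class: str,
    sensor: SensorSpec,
    schedule: PhaseSchedule | None = None,
    rng: np.random.Generator | None = None,
    *,
    depth: float | None = None,
    tau_rise: float = 20.0,
    tau_recovery: float = 60.0,
    noise_cv: float = 0.0,
) -> SensorTransient:
    """Generate one sensor transient for a sample of the given class.

    The response depth defaults to the sensor's sensitivity at the class
    centroid; pass ``depth`` to override.  ``noise_cv`` applies sample-wise
    multiplicative log-normal noise (requires ``rng``).
    """
    schedule = schedule or PhaseSchedule()
    if depth is None:
        if genotype_class not in _CLASS_CENTERS:
            raise ValueError(f"unknown quality class {genotype_class!r}")
        depth = sensor.depth_at(_CLASS_CENTERS[genotype_class])
    if not 0.0 < depth < 1.0:
        raise ValueError(f"response depth must lie in (0, 1), got {depth}")
    t = schedule.times()
    R = _closed_form_curve(t, schedule, sensor.baseline_ohm, depth, tau_rise, tau_recovery)
    if noise_cv > 0:
        if rng is None:
            raise ValueError("noise_cv > 0 requires an rng")
        R = R * np.exp(rng.normal(0.0, noise_cv, size=R.shape))
    return SensorTransient(sensor_id=sensor.sensor_id, t=t, R=R, schedule=schedule)


def generate_dataset(
    config: GeneratorConfig,
) -> tuple[list[Measurement], list[str], list[ConstituentProfile]]:
    """Generate the full measurement set.

    Returns (measurements, labels, constituent table).  Labels come from the
    10 % / 50 % rule applied to the generated composition table, never from
    the configured class layout directly — the generator's totals are drawn
    inside the class ranges, so the two agree by construction.
    """
    profiles = generate_constituent_table(config)
    genotype_labels = label_dataset(profiles)
    coords = _genotype_coords(config)
    measurements: list[Measurement] = []
    labels: list[str] = []
    meas_index = 0
    for gid in config.genotype_ids:
        aroma = coords[gid]
        for rep in range(config.replicates_per_genotype):
            rng = np.random.default_rng([config.rng_seed, meas_index])
            transients: dict[str, SensorTransient] = {}
            for sensor in config.sensors:
                d = sensor.depth_at(aroma)
                if config.depth_jitter_cv > 0:
                    d = d * (1.0 + rng.normal(0.0, config.depth_jitter_cv))
                d = float(np.clip(d, 0.01, 0.95))
                transients[sensor.sensor_id] = generate_transient(
                    genotype_labels[gid],
                    sensor,
                    config.schedule,
                    rng,
                    depth=d,
                    tau_rise=config.tau_rise,
                    tau_recovery=config.tau_recovery,
                    noise_cv=config.noise_cv,
                )
            mid = f"{gid}_r{rep + 1:02d}"
            measurements.append(
                Measurement(measurement_id=mid, genotype=gid, transients=transients)
            )
            labels.append(genotype_labels[gid])
            meas_index += 1
    return measurements, labels, profiles


# ---------------------------------------------------------------------------
# CSV / YAML round-tripping


def write_measurements_csv(measurements: list[Measurement], path) -> None:
    """Long-format export: measurement_id, sensor_id, t_s, resistance_ohm."""
    frames = []
    for m in measurements:
        for sid, tr in sorted(m.transients.items()):
            frames.append(
                pd.DataFrame(
                    {
                        "measurement_id": m.measurement_id,
                        "sensor_id": sid,
                        "t_s": tr.t,
                        "resistance_ohm": tr.R,
                    }
                )
            )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_measurements_csv(path, schedule: PhaseSchedule | None = None) -> list[Measurement]:
    schedule = schedule or PhaseSchedule()
    df = pd.read_csv(path)
    measurements = []
    for mid, grp in df.groupby("measurement_id", sort=False):
        transients = {}
        for sid, sg in grp.groupby("sensor_id", sort=True):
            transients[sid] = SensorTransient(
                sensor_id=sid,
                t=sg["t_s"].to_numpy(),
                R=sg["resistance_ohm"].to_numpy(),
                schedule=schedule,
            )
        genotype = str(mid).rsplit("_", 1)[0]
        measurements.append(
            Measurement(measurement_id=str(mid), genotype=genotype, transients=transients)
        )
    return measurements


def write_labels_csv(measurements: list[Measurement], labels: list[str], path) -> None:
    pd.DataFrame(
        {
            "measurement_id": [m.measurement_id for m in measurements],
            "genotype": [m.genotype for m in measurements],
            "class": labels,
        }
    ).to_csv(path, index=False)


def write_constituent_csv(profiles: list[ConstituentProfile], path) -> None:
    """Constituent rows x genotype columns, mirroring a GC-MS report table."""
    names: list[str] = []
    for p in profiles:
        for n in p.percents:
            if n not in names:
                names.append(n)
    df = pd.DataFrame(
        {p.genotype_id: [p.get(n) for n in names] for p in profiles}, index=names
    )
    df.index.name = "constituent"
    df.to_csv(path)


def config_to_yaml(config: GeneratorConfig, path) -> None:
    doc = {
        "n_genotypes": config.n_genotypes,
        "replicates_per_genotype": config.replicates_per_genotype,
        "noise_cv": config.noise_cv,
        "depth_jitter_cv": config.depth_jitter_cv,
        "tau_rise": config.tau_rise,
        "tau_recovery": config.tau_recovery,
        "rng_seed": config.rng_seed,
        "use_reference_profiles": config.use_reference_profiles,
        "genotype_classes": list(config.genotype_classes),
        "genotype_coords": {g: list(c) for g, c in config.genotype_coords.items()},
        "class_spec": {c: list(r) for c, r in config.class_spec.items()},
        "schedule": {
            "baseline_s": config.schedule.baseline_s,
            "injection_s": config.schedule.injection_s,
            "recovery_s": config.schedule.recovery_s,
            "sample_period_s": config.schedule.sample_period_s,
        },
        "sensors": [
            {
                "sensor_id": s.sensor_id,
                "name": s.name,
                "baseline_ohm": s.baseline_ohm,
                "base_depth": s.base_depth,
                "loadings": list(s.loadings),
            }
            for s in config.sensors
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def config_from_yaml(path) -> GeneratorConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    kwargs = dict(doc)
    if "schedule" in kwargs:
        kwargs["schedule"] = PhaseSchedule(**kwargs["schedule"])
    if "sensors" in kwargs:
        kwargs["sensors"] = tuple(
            SensorSpec(
                sensor_id=s["sensor_id"],
                name=s.get("name", s["sensor_id"]),
                baseline_ohm=s["baseline_ohm"],
                base_depth=s["base_depth"],
                loadings=tuple(s["loadings"]),
            )
            for s in kwargs["sensors"]
        )
    if "genotype_classes" in kwargs:
        kwargs["genotype_classes"] = tuple(kwargs["genotype_classes"])
    if "genotype_coords" in kwargs:
        kwargs["genotype_coords"] = {
            g: tuple(c) for g, c in kwargs["genotype_coords"].items()
        }
    if "class_spec" in kwargs:
        kwargs["class_spec"] = {c: tuple(r) for c, r in kwargs["class_spec"].items()}
    return GeneratorConfig(**kwargs)
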