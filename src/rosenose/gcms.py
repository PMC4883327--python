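"""GC-MS quality labelling of rose essential oils.

The reference method for oil quality is gas chromatography–mass spectrometry:
each genotype's volatile composition is tabulated as percent of total peak
area, and quality is scored by the summed percentage of the six constituents
known to carry the rose aroma (phenyl ethyl alcohol, trans rose oxide,
citronellol, nerol, geraniol, geranial).  The summed percentage maps onto
three coarse quality classes:

* ``C1`` (low)    — total below 10 %
* ``C2`` (middle) — total in [10, 50) %
* ``C3`` (high)   — total of 50 % or more

These class labels are the ground truth against which the e-nose classifiers
are trained and evaluated.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "QUALITY_CLASSES",
    "KEY_CONSTITUENTS",
    "ConstituentProfile",
    "KeyConstituentSet",
    "total_key_constituents",
    "assign_quality_class",
    "label_dataset",
    "load_reference_profiles",
    "read_constituent_csv",
    "write_labels_csv",
]

#: Ordered quality labels, low to high.
QUALITY_CLASSES = ("C1", "C2", "C3")

#: The six aroma-defining volatiles of Rosa damascena oil.
KEY_CONSTITUENTS = (
    "phenyl ethyl alcohol",
    "trans rose oxide",
    "citronellol",
    "nerol",
    "geraniol",
    "geranial",
)

#: Class thresholds on the six-constituent total, percent.
LOW_MIDDLE_THRESHOLD = 10.0
MIDDLE_HIGH_THRESHOLD = 50.0


def _canon(name: str) -> str:
    """Case-insensitive, whitespace-normalised constituent name."""
    return " ".join(name.strip().lower().split())


@dataclass(frozen=True)
class KeyConstituentSet:
    """The set of constituents whose summed percent defines quality."""

    names: tuple[str, ...] = KEY_CONSTITUENTS

    def __post_init__(self) -> None:
        canon = [_canon(n) for n in self.names]
        if len(self.names) != 6:
            raise ValueError(f"expected six key constituents, got {len(self.names)}")
        if len(set(canon)) != len(canon):
            raise ValueError("key constituent names must be distinct")


@dataclass
class ConstituentProfile:
    """One genotype's GC-MS composition (constituent name -> percent).

    Missing constituents (printed as "-" in composition tables) are simply
    absent from the mapping and count as zero.
    """

    genotype_id: str
    percents: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        canon: dict[str, float] = {}
        for name, pct in self.percents.items():
            pct = float(pct)
            if pct < 0:
                raise ValueError(
                    f"{self.genotype_id}: negative percent for {name!r}: {pct}"
                )
            if pct > 100:
                raise ValueError(
                    f"{self.genotype_id}: percent above 100 for {name!r}: {pct}"
                )
            canon[_canon(name)] = pct
        self.percents = canon

    def get(self, name: str) -> float:
        return self.percents.get(_canon(name), 0.0)


def total_key_constituents(
    profile: ConstituentProfile, keys: KeyConstituentSet | None = None
) -> float:
    """Sum the key-constituent percentages of one genotype."""
    keys = keys or KeyConstituentSet()
    return sum(profile.get(name) for name in keys.names)


def assign_quality_class(total: float) -> str:
    """Map a six-constituent total (percent) to a quality class.

    Half-open intervals: [0, 10) -> C1, [10, 50) -> C2, [50, inf) -> C3.
    """
    if total < 0:
        raise ValueError(f"total percent must be nonnegative, got {total}")
    if total < LOW_MIDDLE_THRESHOLD:
        return "C1"
    if total < MIDDLE_HIGH_THRESHOLD:
        return "C2"
    return "C3"


def label_dataset(
    profiles: list[ConstituentProfile], keys: KeyConstituentSet | None = None
) -> dict[str, str]:
    """Assign a quality class to every genotype.

    Raises on an empty list or duplicate genotype ids.
    """
    if not profiles:
        raise ValueError("no profiles to label")
    ids = [p.genotype_id for p in profiles]
    if len(set(ids)) != len(ids):
        dupes = sorted({g for g in ids if ids.count(g) > 1})
        raise ValueError(f"duplicate genotype ids: {dupes}")
    keys = keys or KeyConstituentSet()
    return {
        p.genotype_id: assign_quality_class(total_key_constituents(p, keys))
        for p in profiles
    }


def read_constituent_csv(path) -> list[ConstituentProfile]:
    """Read a composition table (rows = constituents, columns = genotypes).

    "-" or empty cells mean the constituent was not detected (0 %).
    """
    df = pd.read_csv(path, index_col=0)
    df = df.replace("-", 0.0).fillna(0.0).astype(float)
    return [
        ConstituentProfile(genotype_id=str(col), percents=dict(df[col]))
        for col in df.columns
    ]


def load_reference_profiles() -> list[ConstituentProfile]:
    """The packaged GC-MS composition table of the ten Iranian genotypes."""
    ref = importlib.resources.files("rosenose.data") / "rosa_damascena_constituents.csv"
    with importlib.resources.as_file(ref) as path:
        return read_constituent_csv(path)


def write_labels_csv(
    profiles: list[ConstituentProfile], path, keys: KeyConstituentSet | None = None
) -> pd.DataFrame:
    """Write genotype, total_percent, class to CSV; returns the frame."""
    keys = keys or KeyConstituentSet()
    labels = label_dataset(profiles, keys)
    frame = pd.DataFrame(
        {
            "genotype": [p.genotype_id for p in profiles],
            "total_percent": [total_key_constituents(p, keys) for p in profiles],
            "class": [labels[p.genotype_id] for p in profiles],
        }
    )
    frame.to_csv(path, index=False)
    return frame
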