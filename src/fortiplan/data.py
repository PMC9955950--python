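"""Domain types and CSV I/O for food groups, composition matrices, reference
values and individual-level dietary surveys.

The central object is the :class:`CompositionMatrix`: one row per food group
with the population's average intake of that group (g/day) and the group's
current nutrient concentration (µg/g).  It drives the fortification
optimisation.  Individual-level data live in an :class:`IntakeSurvey`
(one record per person × food item, amounts are mean daily grams) and are
used for dispersal and exposure evaluation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationError",
    "FoodGroup",
    "CompositionMatrix",
    "ReferenceBand",
    "ReferenceSet",
    "IntakeSurvey",
    "read_composition",
    "read_reference_values",
    "read_survey",
    "aggregate_composition",
    "person_intake",
]


class ValidationError(ValueError):
    """Raised when an input table violates a domain invariant."""


@dataclass(frozen=True)
class FoodGroup:
    """A food group: an opaque positive-integer ID plus a text label.

    IDs are labels, not indices — groupings may skip IDs.
    """

    group_id: int
    name: str = ""

    def __post_init__(self) -> None:
        if self.group_id <= 0:
            raise ValidationError(f"group_id must be positive, got {self.group_id}")


COMPOSITION_COLUMNS = ["group_id", "average_intake", "current_concentration"]
SURVEY_COLUMNS = ["person_id", "age", "item_id", "group_id", "amount", "item_concentration"]
REFERENCE_COLUMNS = ["age_low", "age_high", "ar", "ri", "ul"]


@dataclass
class CompositionMatrix:
    """Per-food-group average intake (g/day) and nutrient concentration (µg/g).

    Zero-concentration rows are permitted and retained: groups with no current
    nutrient content are still candidates for fortification.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in COMPOSITION_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValidationError(f"composition matrix missing columns: {missing}")
        f = self.frame.loc[:, COMPOSITION_COLUMNS].reset_index(drop=True)
        f["group_id"] = f["group_id"].astype(int)
        f["average_intake"] = f["average_intake"].astype(float)
        f["current_concentration"] = f["current_concentration"].astype(float)
        dup = f["group_id"][f["group_id"].duplicated()]
        if not dup.empty:
            raise ValidationError(f"duplicate group_id: {sorted(dup.unique())}")
        for col in ("average_intake", "current_concentration"):
            bad = f.index[(f[col] < 0) | ~np.isfinite(f[col])]
            if len(bad):
                raise ValidationError(
                    f"{col} must be finite and >= 0; offending rows (0-based): {list(bad)}"
                )
        if (f["group_id"] <= 0).any():
            raise ValidationError("group_id must be positive")
        self.frame = f

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[int, float, float]]
    ) -> "CompositionMatrix":
        """Build from ``(group_id, average_intake, current_concentration)`` tuples."""
        return cls(pd.DataFrame(list(records), columns=COMPOSITION_COLUMNS))

    @property
    def group_ids(self) -> list[int]:
        return self.frame["group_id"].tolist()

    @property
    def intakes(self) -> dict[int, float]:
        return dict(zip(self.frame["group_id"], self.frame["average_intake"]))

    @property
    def concentrations(self) -> dict[int, float]:
        return dict(zip(self.frame["group_id"], self.frame["current_concentration"]))

    def __len__(self) -> int:
        return len(self.frame)

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


@dataclass(frozen=True)
class ReferenceBand:
    """Nutrient reference values for one half-open integer age band [low, high).

    ar
        Average requirement (µg/day) — meets the needs of half the group.
    ri
        Recommended intake (µg/day) — adequate for nearly all individuals.
    ul
        Tolerable upper intake level (µg/day).
    """

    age_low: int
    age_high: int
    ar: float
    ri: float
    ul: float

    def __post_init__(self) -> None:
        if self.age_low >= self.age_high:
            raise ValidationError(f"empty age band [{self.age_low}, {self.age_high})")
        if not (0 < self.ar <= self.ri < self.ul):
            raise ValidationError(
                f"need 0 < AR <= RI < UL, got AR={self.ar} RI={self.ri} UL={self.ul}"
            )

    def contains(self, age: int) -> bool:
        return self.age_low <= age < self.age_high

    @property
    def label(self) -> str:
        return f"{self.age_low}-{self.age_high - 1}"


@dataclass
class ReferenceSet:
    """A set of non-overlapping :class:`ReferenceBand` objects."""

    bands: list[ReferenceBand]

    def __post_init__(self) -> None:
        bands = sorted(self.bands, key=lambda b: b.age_low)
        for a, b in zip(bands, bands[1:]):
            if b.age_low < a.age_high:
                raise ValidationError(
                    f"overlapping age bands: [{a.age_low},{a.age_high}) and "
                    f"[{b.age_low},{b.age_high})"
                )
        self.bands = bands

    def band_for(self, age: int) -> ReferenceBand | None:
        for band in self.bands:
            if band.contains(age):
                return band
        return None

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            [(b.age_low, b.age_high, b.ar, b.ri, b.ul) for b in self.bands],
            columns=REFERENCE_COLUMNS,
        ).to_csv(path, index=False)


@dataclass
class IntakeSurvey:
    """Individual-level dietary survey.

    One record per (person, food item); ``amount`` is the mean daily consumed
    grams over the recording period, ``item_concentration`` the item's current
    nutrient content in µg/g.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SURVEY_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValidationError(f"survey missing columns: {missing}")
        f = self.frame.loc[:, SURVEY_COLUMNS].reset_index(drop=True)
        f["age"] = f["age"].astype(int)
        f["group_id"] = f["group_id"].astype(int)
        f["amount"] = f["amount"].astype(float)
        f["item_concentration"] = f["item_concentration"].astype(float)
        if len(f):
            dup = f.duplicated(subset=["person_id", "item_id"])
            if dup.any():
                pairs = f.loc[dup, ["person_id", "item_id"]].iloc[:3].values.tolist()
                raise ValidationError(f"duplicate (person_id, item_id) pairs, e.g. {pairs}")
            ages = f.groupby("person_id")["age"].nunique()
            unstable = ages[ages > 1]
            if not unstable.empty:
                raise ValidationError(
                    f"persons with inconsistent age: {list(unstable.index[:5])}"
                )
            for col in ("amount", "item_concentration"):
                if (f[col] < 0).any() or not np.isfinite(f[col]).all():
                    raise ValidationError(f"{col} must be finite and >= 0")
        self.frame = f

    @property
    def person_ids(self) -> list:
        return self.frame["person_id"].unique().tolist()

    @property
    def n_persons(self) -> int:
        return self.frame["person_id"].nunique()

    def ages(self) -> pd.Series:
        """Age per person (first record; validated constant)."""
        return self.frame.groupby("person_id")["age"].first()

    def __len__(self) -> int:
        return len(self.frame)

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


def _read_csv(path: str | Path, columns: Sequence[str], what: str) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise ValidationError(f"{what} file {path!s} missing columns: {missing}")
    return frame


def read_composition(path: str | Path) -> CompositionMatrix:
    """Read a composition matrix CSV (``group_id,average_intake,current_concentration``).

    Row order is preserved; an empty file with a header yields an empty matrix.
    """
    return CompositionMatrix(_read_csv(path, COMPOSITION_COLUMNS, "composition"))


def read_reference_values(path: str | Path) -> ReferenceSet:
    """Read reference values CSV (``age_low,age_high,ar,ri,ul``)."""
    frame = _read_csv(path, REFERENCE_COLUMNS, "reference values")
    bands = [
        ReferenceBand(int(r.age_low), int(r.age_high), float(r.ar), float(r.ri), float(r.ul))
        for r in frame.itertuples()
    ]
    return ReferenceSet(bands)


def read_survey(path: str | Path) -> IntakeSurvey:
    """Read an individual-level survey CSV
    (``person_id,age,item_id,group_id,amount,item_concentration``)."""
    return IntakeSurvey(_read_csv(path, SURVEY_COLUMNS, "survey"))


def aggregate_composition(
    survey: IntakeSurvey, weighting: str = "intake_weighted"
) -> CompositionMatrix:
    """Aggregate an item-level survey to a group-level composition matrix.

    Parameters
    ----------
    weighting
        ``"intake_weighted"``: group concentration is total nutrient mass over
        total grams (mass-conserving); average_intake is the mean over all
        surveyed persons of their summed group grams (non-consumers count 0).
        ``"mean_of_item_means"``: average_intake is the mean over items of the
        per-item mean amount among its consumers; concentration the unweighted
        mean of item concentrations.
    """
    if weighting not in ("intake_weighted", "mean_of_item_means"):
        raise ValueError(f"unknown weighting {weighting!r}")
    f = survey.frame
    if f.empty:
        raise ValidationError("cannot aggregate an empty survey")
    rows = []
    n_persons = survey.n_persons
    for gid, g in f.groupby("group_id", sort=True):
        if weighting == "intake_weighted":
            grams = g["amount"].sum()
            mass = (g["amount"] * g["item_concentration"]).sum()
            if grams > 0:
                conc = mass / grams
            else:
                conc = 0.0
                logger.warning("group %s has zero total grams; concentration set to 0", gid)
            intake = grams / n_persons
        else:
            per_item = g.groupby("item_id").agg(
                mean_amount=("amount", "mean"),
                conc=("item_concentration", "mean"),
            )
            intake = per_item["mean_amount"].mean()
            conc = per_item["conc"].mean()
        rows.append((int(gid), float(intake), float(conc)))
    return CompositionMatrix.from_records(rows)


def person_intake(
    survey: IntakeSurvey,
    concentrations: Mapping | pd.Series | None = None,
) -> pd.Series:
    """Total daily nutrient intake (µg/day) per person: Σ amount × concentration.

    ``concentrations`` maps item_id → µg/g.  Items absent from the table fall
    back to the survey's own ``item_concentration``, so passing ``None``
    evaluates the current (unfortified) scenario.  Persons with no records are
    absent from the output.
    """
    f = survey.frame
    conc = f["item_concentration"].to_numpy(dtype=float, copy=True)
    if concentrations is not None:
        table = dict(concentrations.items()) if not isinstance(concentrations, dict) else concentrations
        mapped = f["item_id"].map(table)
        mask = mapped.notna()
        conc[mask.to_numpy()] = mapped[mask].astype(float).to_numpy()
    contrib = pd.Series(f["amount"].to_numpy() * conc, index=f.index)
    out = contrib.groupby(f["person_id"]).sum()
    out.name = "intake"
    return out
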