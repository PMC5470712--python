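"""Choice-set data model, readers, filters, and stage assignment.

The sampling unit of a used-vs-available resource-selection study of this
design is the *choice set*: one location an animal actually used together
with two paired random ("available") locations sampled at the same time,
each described by the same vegetation covariates.  This module defines the
in-memory containers (:class:`Location`, :class:`ChoiceSet`,
:class:`Dataset`), a CSV reader/writer for the canonical one-row-per-location
table, postfledging stage assignment, the one-individual-per-brood filter,
and covariate standardization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("fledgechoice")

#: The six vegetation covariates entering the utility as main effects, in
#: the fixed model order.  Units: litter_depth cm; understory_density
#: proportion of a density board covered (0-1); sapling/pole/saw stem
#: densities in stems/ha for 3.0-12.5, 12.5-27.5 and >27.5 cm DBH classes;
#: canopy_cover percent (0-100).
VEGETATION_COVARIATES: tuple[str, ...] = (
    "litter_depth",
    "understory_density",
    "sapling_density",
    "pole_density",
    "saw_density",
    "canopy_cover",
)

#: Distance to the nearest nonforest edge, metres.
EDGE_COVARIATE = "edge_distance"

ALL_COVARIATES: tuple[str, ...] = VEGETATION_COVARIATES + (EDGE_COVARIATE,)

STAGES = ("nest", "early_dependent", "late_dependent", "independent")
JUVENILE_STAGES = ("early_dependent", "late_dependent", "independent")

#: Canonical CSV columns (one row per location).
TABLE_COLUMNS: tuple[str, ...] = (
    "set_id",
    "species",
    "individual_id",
    "brood_id",
    "stage",
    "day_postfledge",
    "role",
) + ALL_COVARIATES


class SchemaError(ValueError):
    """A required column is missing or a value violates the table contract."""


@dataclass(frozen=True)
class Location:
    """One sampled point with its seven habitat covariates.

    ``role`` is ``"used"`` for the location the bird selected and
    ``"available"`` for the paired random points.
    """

    litter_depth: float
    understory_density: float
    sapling_density: float
    pole_density: float
    saw_density: float
    canopy_cover: float
    edge_distance: float
    role: str = "available"

    def __post_init__(self) -> None:
        if self.role not in ("used", "available"):
            raise ValueError(f"role must be 'used' or 'available', got {self.role!r}")
        for name in ("litter_depth", "sapling_density", "pole_density",
                     "saw_density", "edge_distance"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if not 0.0 <= self.canopy_cover <= 100.0:
            raise ValueError(f"canopy_cover must lie in [0, 100], got {self.canopy_cover}")
        if not np.isfinite(self.understory_density):
            raise ValueError("understory_density must be finite")

    def covariates(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in ALL_COVARIATES}


@dataclass(frozen=True)
class ChoiceSet:
    """One decision instance: three locations, exactly one of them used."""

    set_id: str
    species: str
    individual_id: str
    brood_id: str
    stage: str
    locations: tuple[Location, Location, Location]
    used_index: int
    day_postfledge: int | None = None

    def __post_init__(self) -> None:
        if len(self.locations) != 3:
            raise ValueError("a choice set holds exactly 3 locations")
        roles = [loc.role for loc in self.locations]
        if roles.count("used") != 1:
            raise ValueError("a choice set holds exactly one used location")
        if roles[self.used_index] != "used":
            raise ValueError("used_index does not point at the used location")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.stage == "nest" and self.day_postfledge is not None:
            raise ValueError("nest choice sets carry no day_postfledge")


@dataclass
class Dataset:
    """All choice sets of one species plus the stage -> model-stage map.

    ``stage_grouping`` maps each stage label present in the data to an
    integer model-stage index; pooling stages (e.g. late_dependent and
    independent sharing one population-level distribution) is expressed by
    mapping two labels to the same index.
    """

    sets: list[ChoiceSet]
    species: str
    stage_grouping: dict[str, int] = field(default_factory=dict)
    n_excluded_incomplete: int = 0

    def __post_init__(self) -> None:
        for cs in self.sets:
            if cs.species != self.species:
                raise ValueError("all choice sets must share the dataset species")
        present = {cs.stage for cs in self.sets}
        if not self.stage_grouping:
            self.stage_grouping = {s: i for i, s in enumerate(sorted(present))}
        missing = present - set(self.stage_grouping)
        if missing:
            raise ValueError(f"stages {sorted(missing)} absent from stage_grouping")

    def __len__(self) -> int:
        return len(self.sets)

    def subset(self, stages: Iterable[str]) -> "Dataset":
        keep = set(stages)
        return Dataset(
            sets=[cs for cs in self.sets if cs.stage in keep],
            species=self.species,
            stage_grouping={s: i for s, i in self.stage_grouping.items() if s in keep},
        )

    def individuals(self) -> list[str]:
        seen: dict[str, None] = {}
        for cs in self.sets:
            seen.setdefault(cs.individual_id)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        """Flatten to the canonical one-row-per-location table."""
        rows = []
        for cs in self.sets:
            for loc in cs.locations:
                row = {
                    "set_id": cs.set_id,
                    "species": cs.species,
                    "individual_id": cs.individual_id,
                    "brood_id": cs.brood_id,
                    "stage": cs.stage,
                    "day_postfledge": cs.day_postfledge,
                    "role": loc.role,
                }
                row.update(loc.covariates())
                rows.append(row)
        return pd.DataFrame(rows, columns=list(TABLE_COLUMNS))

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def assign_stage(day_postfledge: int, independent: bool = False) -> str:
    """Postfledging stage from days since leaving the nest.

    Birds still fed by parents are early dependent through their first week
    out of the nest (day <= 7) and late dependent from day 8 on; a bird no
    longer receiving parental care is independent regardless of day.
    """
    if day_postfledge < 0:
        raise ValueError(f"day_postfledge must be >= 0, got {day_postfledge}")
    if independent:
        return "independent"
    return "early_dependent" if day_postfledge <= 7 else "late_dependent"


def _group_rows(df: pd.DataFrame, species: str | None) -> tuple[list[ChoiceSet], int]:
    sets: list[ChoiceSet] = []
    n_excluded = 0
    for set_id, g in df.groupby("set_id", sort=True):
        if len(g) != 3:
            n_excluded += 1
            continue
        roles = list(g["role"])
        if roles.count("used") != 1:
            raise SchemaError(f"set {set_id!r} has {roles.count('used')} used rows; expected 1")
        for col in ("species", "individual_id", "brood_id", "stage"):
            if g[col].nunique() != 1:
                raise SchemaError(f"set {set_id!r} mixes values in column {col!r}")
        locs = tuple(
            Location(role=row["role"], **{c: float(row[c]) for c in ALL_COVARIATES})
            for _, row in g.iterrows()
        )
        day = g["day_postfledge"].iloc[0]
        day = None if pd.isna(day) else int(day)
        sets.append(
            ChoiceSet(
                set_id=str(set_id),
                species=str(g["species"].iloc[0]),
                individual_id=str(g["individual_id"].iloc[0]),
                brood_id=str(g["brood_id"].iloc[0]),
                stage=str(g["stage"].iloc[0]),
                day_postfledge=day,
                locations=locs,  # type: ignore[arg-type]
                used_index=roles.index("used"),
            )
        )
    return sets, n_excluded


def read_choice_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    understory_unit: str = "proportion",
) -> Dataset:
    """Read a canonical choice-set CSV into a :class:`Dataset`.

    Parameters
    ----------
    path
        Delimited-text file with one row per location and a header row.
    schema
        Optional mapping from the file's column names to the canonical
        names in :data:`TABLE_COLUMNS`.
    understory_unit
        ``"proportion"`` (0-1 density-board scores, the default) or
        ``"percent"``; percent scores are divided by 100 on ingest.

    Sets with a row count other than 3 are excluded and counted in the
    returned dataset's ``n_excluded_incomplete``; a set with duplicate used
    rows raises :class:`SchemaError`.
    """
    df = pd.read_csv(path)
    if schema:
        df = df.rename(columns=dict(schema))
    required = [c for c in TABLE_COLUMNS if c != "day_postfledge"]
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"required column {col!r} missing from {path}")
    if "day_postfledge" not in df.columns:
        df["day_postfledge"] = np.nan
    if understory_unit == "percent":
        df = df.assign(understory_density=df["understory_density"] / 100.0)
    elif understory_unit != "proportion":
        raise ValueError("understory_unit must be 'proportion' or 'percent'")

    species = df["species"].unique()
    if len(species) != 1:
        raise SchemaError(f"table mixes species {sorted(species)}; one species per dataset")
    sets, n_excluded = _group_rows(df, str(species[0]))
    if n_excluded:
        logger.info("excluded %d incomplete choice set(s) (!= 3 rows)", n_excluded)
    return Dataset(sets=sets, species=str(species[0]),
                   n_excluded_incomplete=n_excluded)


def convert_spreadsheet(xlsx_path: str | Path, csv_path: str | Path,
                        sheet: int | str = 0) -> Path:
    """Convert a spreadsheet export (e.g. a deposited XLSX data file) to the
    delimited-text form :func:`read_choice_table` consumes."""
    df = pd.read_excel(xlsx_path, sheet_name=sheet)
    df.to_csv(csv_path, index=False)
    return Path(csv_path)


def filter_one_per_brood(dataset: Dataset, seed: int) -> Dataset:
    """Keep one tracked individual per brood, chosen by a seeded uniform draw.

    Siblings share habitat exposure, so broods with more than one
    radio-tagged bird would otherwise contribute correlated choice sets.
    Deterministic given ``seed``; broods with a single individual pass
    through unchanged.
    """
    rng = np.random.default_rng(seed)
    brood_members: dict[str, list[str]] = {}
    for cs in dataset.sets:
        members = brood_members.setdefault(cs.brood_id, [])
        if cs.individual_id not in members:
            members.append(cs.individual_id)
    keep: set[str] = set()
    for brood in sorted(brood_members):
        members = brood_members[brood]
        keep.add(members[rng.integers(len(members))])
    return Dataset(
        sets=[cs for cs in dataset.sets if cs.individual_id in keep],
        species=dataset.species,
        stage_grouping=dict(dataset.stage_grouping),
    )


@dataclass(frozen=True)
class ScalingRecord:
    """Pooled means/SDs used to z-score covariates, kept so ratios and
    probability-of-use curves can be mapped back to field scales."""

    means: dict[str, float]
    sds: dict[str, float]
    scheme: str = "zscore"

    def transform(self, name: str, value: float | np.ndarray):
        if self.scheme == "none":
            return value
        return (value - self.means[name]) / self.sds[name]

    def inverse(self, name: str, value: float | np.ndarray):
        if self.scheme == "none":
            return value
        return value * self.sds[name] + self.means[name]


def standardize_covariates(
    dataset: Dataset, scheme: str = "zscore"
) -> tuple[Dataset, ScalingRecord]:
    """Z-score all seven covariates by pooled mean/SD over every location.

    ``scheme="none"`` returns the dataset unchanged with an identity record.
    Standardized values may leave the raw-scale validity ranges, so the
    transformed locations are rebuilt without range validation.
    """
    if not dataset.sets:
        raise ValueError("cannot standardize an empty dataset")
    if scheme == "none":
        record = ScalingRecord(
            means={c: 0.0 for c in ALL_COVARIATES},
            sds={c: 1.0 for c in ALL_COVARIATES},
            scheme="none",
        )
        return dataset, record
    if scheme != "zscore":
        raise ValueError("scheme must be 'none' or 'zscore'")

    frame = dataset.to_frame()
    means, sds = {}, {}
    for c in ALL_COVARIATES:
        vals = frame[c].to_numpy(dtype=float)
        mu, sd = float(vals.mean()), float(vals.std(ddof=0))
        if sd == 0.0:
            raise ValueError(f"covariate {c!r} has zero variance; cannot z-score")
        means[c], sds[c] = mu, sd
    record = ScalingRecord(means=means, sds=sds, scheme="zscore")

    new_sets = []
    for cs in dataset.sets:
        new_locs = tuple(
            _unchecked_location(
                {c: (getattr(loc, c) - means[c]) / sds[c] for c in ALL_COVARIATES},
                loc.role,
            )
            for loc in cs.locations
        )
        new_sets.append(replace(cs, locations=new_locs))
    return (
        Dataset(sets=new_sets, species=dataset.species,
                stage_grouping=dict(dataset.stage_grouping),
                n_excluded_incomplete=dataset.n_excluded_incomplete),
        record,
    )


def _unchecked_location(covs: dict[str, float], role: str) -> Location:
    # bypass __post_init__ range checks: z-scored values are legitimately
    # negative / outside field ranges
    loc = object.__new__(Location)
    for name, value in covs.items():
        object.__setattr__(loc, name, float(value))
    object.__setattr__(loc, "role", role)
    return loc
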