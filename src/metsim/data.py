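"""Longitudinal study data: containers, aggregation and tidy-CSV IO.

The on-disk format is a tidy long CSV with columns
``group, animal_id, day, observable, value, unit``; units must match
the observable registry (:data:`metsim.model.OBSERVABLE_UNITS`).
Group-level means/SDs are aggregated from individuals, or series can be
constructed directly from (day, mean, sd, n) vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import OBSERVABLE_UNITS

__all__ = [
    "ObservationSeries",
    "GroupData",
    "StudyDataset",
    "load_study_data",
    "save_study_data",
    "StudyDataError",
]

CSV_COLUMNS = ("group", "animal_id", "day", "observable", "value", "unit")


class StudyDataError(ValueError):
    """Malformed study data (schema, units, duplicate times...)."""


@dataclass
class ObservationSeries:
    """One observable in one group: (day, mean, sd, n) vectors."""

    days: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n: np.ndarray

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        self.n = np.asarray(self.n, dtype=int)
        if not (len(self.days) == len(self.mean) == len(self.sd)
                == len(self.n)):
            raise StudyDataError("series vectors must have equal length")
        if len(self.days) == 0:
            raise StudyDataError("empty observation series")
        if np.any(np.diff(self.days) <= 0):
            raise StudyDataError("observation days must be sorted and unique")
        if np.any(self.sd < 0):
            raise StudyDataError("negative SD")

    def __len__(self) -> int:
        return len(self.days)

    def at_day(self, day: float, atol: float = 0.5):
        """(mean, sd) at the observation closest to ``day`` within atol."""
        i = int(np.argmin(np.abs(self.days - day)))
        if abs(self.days[i] - day) > atol:
            raise KeyError(f"no observation within {atol} days of {day}")
        return float(self.mean[i]), float(self.sd[i])


@dataclass
class GroupData:
    """All observables of one study group."""

    name: str
    observables: dict[str, ObservationSeries] = field(default_factory=dict)
    individuals: pd.DataFrame | None = None  # tidy per-animal rows

    def days_union(self) -> np.ndarray:
        days = sorted({float(d) for s in self.observables.values()
                       for d in s.days})
        return np.array(days)


@dataclass
class StudyDataset:
    """Longitudinal observations per group, per observable."""

    groups: dict[str, GroupData] = field(default_factory=dict)

    def group(self, name: str | None = None) -> GroupData:
        if name is None:
            if len(self.groups) != 1:
                raise KeyError(
                    f"dataset has groups {sorted(self.groups)}; "
                    "specify which one")
            return next(iter(self.groups.values()))
        try:
            return self.groups[name]
        except KeyError:
            raise KeyError(
                f"unknown group {name!r}; have {sorted(self.groups)}") from None

    def subset(self, group: str) -> "StudyDataset":
        return StudyDataset({group: self.group(group)})

    @property
    def group_names(self) -> list[str]:
        return sorted(self.groups)


def _aggregate(df: pd.DataFrame) -> StudyDataset:
    """Per-group mean/SD aggregation of tidy individual rows."""
    groups: dict[str, GroupData] = {}
    for gname, gdf in df.groupby("group", sort=True):
        observables: dict[str, ObservationSeries] = {}
        for obs, odf in gdf.groupby("observable", sort=True):
            agg = (odf.groupby("day")["value"]
                   .agg(["mean", "std", "count"]).reset_index()
                   .sort_values("day"))
            sd = agg["std"].to_numpy()
            sd = np.where(np.isnan(sd), 0.0, sd)
            observables[obs] = ObservationSeries(
                agg["day"].to_numpy(), agg["mean"].to_numpy(),
                sd, agg["count"].to_numpy())
        groups[str(gname)] = GroupData(str(gname), observables,
                                       gdf.reset_index(drop=True))
    return StudyDataset(groups)


def dataset_from_individuals(df: pd.DataFrame) -> StudyDataset:
    """Build a dataset from a tidy per-animal DataFrame (validated)."""
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise StudyDataError(f"missing columns: {missing}")
    unknown_obs = sorted(set(df["observable"]) - set(OBSERVABLE_UNITS))
    if unknown_obs:
        raise StudyDataError(f"unknown observables: {unknown_obs}")
    for i, row in enumerate(df.itertuples(index=False)):
        expected = OBSERVABLE_UNITS[row.observable]
        if row.unit != expected:
            raise StudyDataError(
                f"row {i}: observable {row.observable!r} has unit "
                f"{row.unit!r}, expected {expected!r}")
    dup = df.duplicated(subset=["group", "animal_id", "day", "observable"])
    if dup.any():
        i = int(np.argmax(dup.to_numpy()))
        raise StudyDataError(f"duplicate measurement at row {i}")
    return _aggregate(df)


def load_study_data(path) -> StudyDataset:
    """Read a tidy long CSV and aggregate per-group means/SDs."""
    df = pd.read_csv(path)
    return dataset_from_individuals(df)


def save_study_data(dataset: StudyDataset, path) -> None:
    """Write per-individual rows back to tidy CSV (requires individuals)."""
    frames = []
    for g in dataset.groups.values():
        if g.individuals is None:
            raise StudyDataError(
                f"group {g.name!r} has no per-individual data to write")
        frames.append(g.individuals[list(CSV_COLUMNS)])
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
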