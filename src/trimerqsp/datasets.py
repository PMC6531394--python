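"""Longitudinal study datasets and their CSV dialect.

A :class:`Dataset` is a thin, validated wrapper around a pandas DataFrame
with one row per observation: animal/subject id, group label, dose with
unit, time with unit, the observed value, its type, and a censoring flag
for values below an assay or caliper limit.  Times and doses are kept in
their declared units on disk and normalized on demand (hours, mg/kg).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import HOURS_PER_DAY
from .errors import SchemaError

__all__ = ["Dataset", "OBS_TYPES", "read_dataset", "write_dataset"]

REQUIRED_COLUMNS = [
    "id", "group", "dose", "dose_unit", "time", "time_unit", "obs", "obs_type", "censored",
]
OBS_TYPES = {"tumor_volume", "serum_conc", "tumor_conc", "til_count"}
_TIME_FACTORS = {"h": 1.0, "hour": 1.0, "day": HOURS_PER_DAY, "d": HOURS_PER_DAY}
_DOSE_FACTORS = {"mg/kg": 1.0, "ug/kg": 1e-3, "μg/kg": 1e-3}


@dataclass
class Dataset:
    """Validated longitudinal observations.

    ``realized`` optionally carries the simulated ground truth per
    individual (set by the synthetic-data generators, not serialized to
    CSV); it lets recovery studies compare estimates with the parameters
    actually drawn for the study rather than the population values.
    """

    table: pd.DataFrame
    realized: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"dataset is missing columns: {missing}")
        bad_type = ~df["obs_type"].isin(OBS_TYPES)
        if bad_type.any():
            row = int(np.flatnonzero(bad_type.to_numpy())[0])
            raise SchemaError(
                f"row {row}: unknown obs_type {df['obs_type'].iloc[row]!r} "
                f"(expected one of {sorted(OBS_TYPES)})"
            )
        bad_time = ~df["time_unit"].isin(_TIME_FACTORS)
        if bad_time.any():
            row = int(np.flatnonzero(bad_time.to_numpy())[0])
            raise SchemaError(f"row {row}: unknown time_unit {df['time_unit'].iloc[row]!r}")
        bad_dose = ~df["dose_unit"].isin(_DOSE_FACTORS)
        if bad_dose.any():
            row = int(np.flatnonzero(bad_dose.to_numpy())[0])
            raise SchemaError(f"row {row}: unknown dose_unit {df['dose_unit'].iloc[row]!r}")
        times = pd.to_numeric(df["time"], errors="coerce")
        if times.isna().any() or (times < 0).any():
            row = int(np.flatnonzero((times.isna() | (times < 0)).to_numpy())[0])
            raise SchemaError(f"row {row}: time must be a nonnegative number")

    # -- normalized accessors -------------------------------------------------

    @property
    def time_h(self) -> pd.Series:
        """Observation times in hours."""
        return self.table["time"].astype(float) * self.table["time_unit"].map(_TIME_FACTORS)

    @property
    def dose_mg_per_kg(self) -> pd.Series:
        """Dose levels in mg/kg."""
        return self.table["dose"].astype(float) * self.table["dose_unit"].map(_DOSE_FACTORS)

    def of_type(self, obs_type: str) -> "Dataset":
        if obs_type not in OBS_TYPES:
            raise SchemaError(f"unknown obs_type {obs_type!r}")
        return Dataset(self.table[self.table["obs_type"] == obs_type].reset_index(drop=True))

    def individuals(self) -> list:
        return sorted(self.table["id"].unique())

    def __len__(self) -> int:
        return len(self.table)


def read_dataset(path: str | Path) -> Dataset:
    """Read the CSV dialect; raises :class:`SchemaError` with the offending
    row for malformed files."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"dataset file not found: {path}")
    df = pd.read_csv(path)
    df["censored"] = df.get("censored", False)
    if df["censored"].dtype == object:
        df["censored"] = df["censored"].astype(str).str.lower().isin({"true", "1", "yes"})
    return Dataset(df)


def write_dataset(dataset: Dataset, path: str | Path) -> None:
    """Write the dataset back to CSV, losslessly round-trippable."""
    dataset.table.to_csv(path, index=False)
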