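"""Domain tables, season calendar, and validated CSV/JSON readers and writers.

Collections are plain :class:`pandas.DataFrame` objects with fixed schemas;
the dataclasses below document the row types and are used when building
records programmatically.  All dates are ISO-8601.  Missing core fields cause
a row to be dropped (with a logged count), never imputed.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import logging
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Calendar months belonging to the dry season (November-April).
DRY_MONTHS = frozenset({11, 12, 1, 2, 3, 4})
#: Calendar months belonging to the wet season (May-October).
WET_MONTHS = frozenset({5, 6, 7, 8, 9, 10})

SEASONS = ("dry", "wet")

MEASUREMENT_COLUMNS = [
    "stand_id",
    "plot_id",
    "collar_id",
    "date",
    "rs",
    "soil_temp_10cm",
    "soil_moisture",
]
CLIMATE_COLUMNS = ["stand_id", "date", "air_temp", "precip", "rh"]
CHEMISTRY_COLUMNS = ["stand_id", "season", "ph", "som", "soc", "tn", "tp", "an", "ap"]

#: Declared round-trip precision (decimal places) per column.
_PRECISION = {
    "rs": 4,
    "soil_temp_10cm": 2,
    "air_temp": 2,
    "soil_moisture": 2,
    "precip": 2,
    "rh": 2,
    "ph": 2,
    "som": 2,
    "soc": 2,
    "tn": 2,
    "tp": 2,
    "an": 2,
    "ap": 2,
}


class SchemaError(ValueError):
    """A file does not have the expected columns."""


class ValidationError(ValueError):
    """Rows violate a schema invariant; the message names the rows."""


@dataclasses.dataclass(frozen=True)
class FluxMeasurement:
    """One collar-level respiration observation."""

    stand_id: str
    plot_id: str
    collar_id: str
    date: dt.date
    rs: float  # umol CO2 m-2 s-1
    soil_temp_10cm: float  # degC at 10 cm depth
    soil_moisture: float  # volumetric %, 0-10 cm layer


@dataclasses.dataclass(frozen=True)
class DailyClimate:
    """One stand-day weather-station record."""

    stand_id: str
    date: dt.date
    air_temp: float  # daily mean degC
    precip: float  # mm d-1
    rh: float  # relative humidity %


@dataclasses.dataclass(frozen=True)
class SoilChemistry:
    """Per-stand, per-season topsoil chemistry."""

    stand_id: str
    season: str  # "dry" | "wet"
    ph: float
    som: float  # g kg-1
    soc: float  # g kg-1
    tn: float  # g kg-1
    tp: float  # g kg-1
    an: float  # mg kg-1
    ap: float  # mg kg-1


def assign_season(date) -> str:
    """Return ``"wet"`` for May-October dates, ``"dry"`` for November-April.

    Accepts :class:`datetime.date`, :class:`pandas.Timestamp`, or an ISO-8601
    string.  Season membership depends only on the calendar month.
    """
    if isinstance(date, str):
        date = dt.date.fromisoformat(date)
    month = date.month
    return "wet" if month in WET_MONTHS else "dry"


def season_months(label: str) -> frozenset:
    """Months belonging to a season label."""
    if label == "dry":
        return DRY_MONTHS
    if label == "wet":
        return WET_MONTHS
    raise ValueError(f"unknown season label: {label!r}")


def records_to_frame(records) -> pd.DataFrame:
    """Build a DataFrame from an iterable of the dataclasses above."""
    rows = [dataclasses.asdict(r) for r in records]
    df = pd.DataFrame(rows)
    if "date" in df.columns:
        df["date"] = pd.to_datetime(df["date"])
    return df


def _check_columns(df: pd.DataFrame, expected, path) -> None:
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}; expected {expected}")


def _drop_incomplete(df: pd.DataFrame, columns, path) -> pd.DataFrame:
    incomplete = df[columns].isna().any(axis=1)
    if incomplete.any():
        log.warning("%s: dropped %d row(s) with missing fields", path, int(incomplete.sum()))
        df = df.loc[~incomplete].reset_index(drop=True)
    return df


def _fail_rows(mask: pd.Series, what: str, path) -> None:
    """Raise ValidationError naming the offending file rows (header = line 1)."""
    if mask.any():
        rows = [int(i) + 2 for i in np.flatnonzero(mask.to_numpy())]
        raise ValidationError(f"{path}: {what} in row(s) {rows}")


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".json":
        return pd.read_json(path)
    return pd.read_csv(path)


def read_measurements(path) -> pd.DataFrame:
    """Read and validate a collar measurement table (CSV or JSON).

    Raises :class:`SchemaError` for missing columns and
    :class:`ValidationError` (naming row numbers) for invariant breaches:
    rs finite and >= 0, moisture in [0, 100], temperature in [-10, 60],
    unique (stand_id, collar_id, date).
    """
    df = _read_table(path)
    _check_columns(df, MEASUREMENT_COLUMNS, path)
    df = df[MEASUREMENT_COLUMNS].copy()
    df["date"] = pd.to_datetime(df["date"], format="ISO8601")
    for col in ("rs", "soil_temp_10cm", "soil_moisture"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df = _drop_incomplete(df, ["rs", "soil_temp_10cm", "soil_moisture"], path)
    _fail_rows(~np.isfinite(df["rs"]) | (df["rs"] < 0), "rs not finite and >= 0", path)
    _fail_rows(
        (df["soil_moisture"] < 0) | (df["soil_moisture"] > 100),
        "soil_moisture outside [0, 100]",
        path,
    )
    _fail_rows(
        (df["soil_temp_10cm"] < -10) | (df["soil_temp_10cm"] > 60),
        "soil_temp_10cm outside [-10, 60]",
        path,
    )
    _fail_rows(
        df.duplicated(subset=["stand_id", "collar_id", "date"], keep=False),
        "duplicate (stand_id, collar_id, date)",
        path,
    )
    return df


def read_climate(path) -> pd.DataFrame:
    """Read and validate a daily climate table (one record per stand-date)."""
    df = _read_table(path)
    _check_columns(df, CLIMATE_COLUMNS, path)
    df = df[CLIMATE_COLUMNS].copy()
    df["date"] = pd.to_datetime(df["date"], format="ISO8601")
    for col in ("air_temp", "precip", "rh"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df = _drop_incomplete(df, ["air_temp", "precip", "rh"], path)
    _fail_rows(df["precip"] < 0, "precip < 0", path)
    _fail_rows((df["rh"] < 0) | (df["rh"] > 100), "rh outside [0, 100]", path)
    _fail_rows(
        df.duplicated(subset=["stand_id", "date"], keep=False),
        "duplicate (stand_id, date)",
        path,
    )
    return df


def read_chemistry(path) -> pd.DataFrame:
    """Read and validate a per-season soil chemistry table."""
    df = _read_table(path)
    _check_columns(df, CHEMISTRY_COLUMNS, path)
    df = df[CHEMISTRY_COLUMNS].copy()
    num = ["ph", "som", "soc", "tn", "tp", "an", "ap"]
    for col in num:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df = _drop_incomplete(df, num, path)
    _fail_rows(~df["season"].isin(SEASONS), "season not in {dry, wet}", path)
    _fail_rows((df["ph"] <= 0) | (df["ph"] >= 14), "ph outside (0, 14)", path)
    for col in ("som", "soc", "tn", "tp", "an", "ap"):
        _fail_rows(df[col] <= 0, f"{col} <= 0", path)
    _fail_rows(df["soc"] >= df["som"], "soc >= som", path)
    return df


def _write_table(df: pd.DataFrame, path, columns) -> None:
    path = Path(path)
    out = df[columns].copy()
    if "date" in out.columns:
        out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    for col, nd in _PRECISION.items():
        if col in out.columns:
            out[col] = out[col].astype(float).round(nd)
    if path.suffix == ".json":
        out.to_json(path, orient="records", indent=1)
    else:
        out.to_csv(path, index=False)


def write_measurements(df: pd.DataFrame, path) -> None:
    """Write a measurement table; rates at 4 decimals, temperatures at 2."""
    _write_table(df, path, MEASUREMENT_COLUMNS)


def write_climate(df: pd.DataFrame, path) -> None:
    _write_table(df, path, CLIMATE_COLUMNS)


def write_chemistry(df: pd.DataFrame, path) -> None:
    _write_table(df, path, CHEMISTRY_COLUMNS)


def monthly_mean(df: pd.DataFrame, variable: str) -> pd.DataFrame:
    """Per-stand, per-calendar-month mean of one measurement variable.

    Returns a frame with columns ``stand_id, month, mean, sd, n`` where
    ``month`` is a ``YYYY-MM`` string.  Groups without data are absent, not
    zero-filled; ``sd`` uses ddof=1 (NaN for singleton groups).
    """
    if variable not in df.columns:
        raise ValueError(f"unknown variable: {variable!r}")
    if df.empty:
        raise ValueError("no records to aggregate")
    month = pd.to_datetime(df["date"]).dt.strftime("%Y-%m")
    grouped = df.groupby([df["stand_id"], month.rename("month")])[variable]
    out = grouped.agg(mean="mean", sd="std", n="count").reset_index()
    return out
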