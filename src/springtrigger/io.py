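"""Date-indexed series containers and CSV input/output.

Two containers cover the study's data structure: :class:`DailySeries` for
daily-averaged sea-surface temperature (one value per calendar day, missing
days simply absent) and :class:`SampleSeries` for irregularly collected
fish-egg tow counts, optionally with per-species columns.

CSV dialects
------------
SST raw log     header ``timestamp,temp_c`` — ISO-8601 timestamps, sub-daily;
                readings are averaged per calendar day on read.
SST daily       header ``date,temp_c`` — ISO dates, at most one row per day.
Egg collections header ``date,total_eggs[,<species>...]`` — irregular dates;
                species columns are nonnegative integer counts whose row sum
                may not exceed the total (unidentified eggs are allowed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DailySeries",
    "SampleSeries",
    "read_sst",
    "read_eggs",
    "write_sst",
    "write_eggs",
    "moving_average",
]


def _as_day_index(dates) -> pd.DatetimeIndex:
    idx = pd.DatetimeIndex(pd.to_datetime(dates)).normalize()
    return idx


@dataclass(frozen=True)
class DailySeries:
    """A date-indexed daily series (SST in °C, or any daily covariate).

    Dates are strictly increasing with at most one value per date; missing
    days are absent, never filled or interpolated implicitly.
    """

    data: pd.Series
    label: str = ""

    def __post_init__(self):
        s = self.data
        if not isinstance(s, pd.Series):
            raise TypeError("DailySeries.data must be a pandas Series; use from_pairs()")
        idx = _as_day_index(s.index)
        s = pd.Series(np.asarray(s.to_numpy(), dtype=float), index=idx)
        if len(s) and not idx.is_monotonic_increasing:
            s = s.sort_index()
            idx = s.index
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ValueError(f"duplicate date in daily series: {dup.date()}")
        if np.isnan(s.to_numpy()).any():
            raise ValueError("daily series may not contain NaN values")
        object.__setattr__(self, "data", s)

    @classmethod
    def from_pairs(cls, dates, values, label: str = "") -> "DailySeries":
        return cls(pd.Series(np.asarray(values, dtype=float), index=_as_day_index(dates)), label)

    @property
    def dates(self) -> pd.DatetimeIndex:
        return self.data.index

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def __len__(self) -> int:
        return len(self.data)

    def between(self, start, end) -> pd.Series:
        """Values with start <= date <= end (both inclusive)."""
        return self.data.loc[pd.Timestamp(start) : pd.Timestamp(end)]


@dataclass(frozen=True)
class SampleSeries:
    """Irregularly dated nonnegative egg counts per tow.

    ``species`` (optional) holds per-species nonnegative integer counts on
    the same date index; row sums must not exceed the total count.
    """

    data: pd.Series
    species: Optional[pd.DataFrame] = None
    label: str = ""

    def __post_init__(self):
        s = self.data
        idx = _as_day_index(s.index)
        s = pd.Series(np.asarray(s.to_numpy(), dtype=float), index=idx)
        if len(s) and not idx.is_monotonic_increasing:
            order = np.argsort(idx.values, kind="stable")
            s = s.iloc[order]
            if self.species is not None:
                object.__setattr__(self, "species", self.species.iloc[order])
            idx = s.index
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ValueError(f"duplicate collection date: {dup.date()}")
        vals = s.to_numpy()
        if np.isnan(vals).any() or (vals < 0).any():
            raise ValueError("egg counts must be nonnegative and non-missing")
        if self.species is not None:
            sp = self.species.copy()
            sp.index = idx
            counts = sp.to_numpy()
            if (counts < 0).any():
                raise ValueError("species counts must be nonnegative")
            if not np.allclose(counts, np.round(counts)):
                raise ValueError("species counts must be integers")
            excess = counts.sum(axis=1) > vals + 1e-9
            if excess.any():
                d = idx[np.argmax(excess)]
                raise ValueError(
                    f"species counts exceed total_eggs on {d.date()}"
                )
            object.__setattr__(self, "species", sp)
        object.__setattr__(self, "data", s)

    @classmethod
    def from_pairs(cls, dates, values, species=None, label: str = "") -> "SampleSeries":
        return cls(pd.Series(np.asarray(values, dtype=float), index=_as_day_index(dates)), species, label)

    @property
    def dates(self) -> pd.DatetimeIndex:
        return self.data.index

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def __len__(self) -> int:
        return len(self.data)

    def between(self, start, end) -> pd.Series:
        return self.data.loc[pd.Timestamp(start) : pd.Timestamp(end)]


# ---------------------------------------------------------------------------
# CSV readers / writers
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}; found {list(df.columns)}")


def _parse_numeric(raw: pd.Series, path, colname: str) -> np.ndarray:
    # float() parsing is exact (shortest-repr round-trip), unlike the fast
    # csv float path; files written by this module re-read bit-identically
    out = np.empty(len(raw))
    for k, v in enumerate(raw.to_numpy()):
        try:
            out[k] = float(v)
        except (TypeError, ValueError):
            raise ValueError(
                f"{path}: non-numeric {colname} at line {k + 2}: {v!r}"
            ) from None
        if not np.isfinite(out[k]):
            raise ValueError(f"{path}: missing or non-finite {colname} at line {k + 2}")
    return out


def _parse_dates(raw: pd.Series, path) -> pd.DatetimeIndex:
    dt = pd.to_datetime(raw, errors="coerce", format="ISO8601")
    if dt.isna().any():
        row = int(np.argmax(dt.isna().to_numpy())) + 2
        raise ValueError(f"{path}: unparseable date at line {row}: {raw.iloc[row - 2]!r}")
    return pd.DatetimeIndex(dt)


def read_sst(path, dialect: str = "daily") -> DailySeries:
    """Read an SST CSV; ``raw_log`` rows are averaged per calendar day.

    The raw-log dialect has (timestamp, temp_c) rows every few minutes; the
    daily mean is the arithmetic mean of all readings sharing a calendar
    date (local time, no timezone arithmetic). The daily dialect passes
    through but rejects duplicate dates.
    """
    if dialect not in ("raw_log", "daily"):
        raise ValueError(f"unknown SST dialect {dialect!r}; expected 'raw_log' or 'daily'")
    df = pd.read_csv(path, dtype=str)
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    if dialect == "raw_log":
        _require_columns(df, ["timestamp", "temp_c"], path)
        when = _parse_dates(df["timestamp"], path)
        temps = _parse_numeric(df["temp_c"], path, "temp_c")
        daily = pd.Series(temps, index=when.normalize()).groupby(level=0).mean()
        return DailySeries(daily.sort_index(), label="sst")
    _require_columns(df, ["date", "temp_c"], path)
    dates = _parse_dates(df["date"], path).normalize()
    if dates.has_duplicates:
        dup = dates[dates.duplicated()][0]
        raise ValueError(f"{path}: duplicate date {dup.date()} in daily dialect")
    temps = _parse_numeric(df["temp_c"], path, "temp_c")
    return DailySeries(pd.Series(temps, index=dates), label="sst")


def read_eggs(path) -> SampleSeries:
    """Read an egg-collection CSV with optional per-species columns."""
    df = pd.read_csv(path, dtype=str)
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    _require_columns(df, ["date", "total_eggs"], path)
    dates = _parse_dates(df["date"], path).normalize()
    totals = _parse_numeric(df["total_eggs"], path, "total_eggs")
    if (totals < 0).any():
        row = int(np.argmax(totals < 0)) + 2
        raise ValueError(f"{path}: negative total_eggs at line {row}")
    species_cols = [c for c in df.columns if c not in ("date", "total_eggs")]
    species = None
    if species_cols:
        sp = pd.DataFrame(
            {c: _parse_numeric(df[c], path, c) for c in species_cols}
        )
        sp.index = dates
        species = sp
    return SampleSeries(pd.Series(totals, index=dates), species=species, label="eggs")


def write_sst(series: DailySeries, path) -> None:
    """Write a daily-dialect SST CSV (round-trips bit-identically)."""
    out = pd.DataFrame(
        {"date": series.dates.strftime("%Y-%m-%d"), "temp_c": series.values}
    )
    out.to_csv(path, index=False)


def write_eggs(series: SampleSeries, path) -> None:
    out = pd.DataFrame({"date": series.dates.strftime("%Y-%m-%d")})
    out["total_eggs"] = series.values
    if series.species is not None:
        for c in series.species.columns:
            out[c] = series.species[c].to_numpy()
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Smoothing
# ---------------------------------------------------------------------------

def moving_average(series: DailySeries, width: int, alignment: str = "centered") -> DailySeries:
    """Centered moving average over calendar days.

    The value at date t is the mean of available values within
    ``[t − (width−1)/2, t + (width−1)/2]``, provided at least half of the
    window days carry a value; otherwise that date is absent from the
    output. ``width=1`` returns the input unchanged. Missing days inside a
    window are skipped, never interpolated.
    """
    if alignment != "centered":
        raise ValueError(f"unsupported alignment {alignment!r}")
    width = int(width)
    if width < 1 or width % 2 == 0:
        raise ValueError(f"width must be a positive odd integer, got {width}")
    if width == 1 or len(series) == 0:
        return DailySeries(series.data.copy(), series.label)
    full = pd.date_range(series.dates[0], series.dates[-1], freq="D")
    dense = series.data.reindex(full)
    min_periods = (width + 1) // 2  # >= 50% of window days present
    sm = dense.rolling(window=width, center=True, min_periods=min_periods).mean()
    sm = sm.dropna()
    return DailySeries(sm, series.label)
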