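"""Spring temperature trigger (STT), peak summer eggs, and the linear model.

The STT is a per-year scalar event statistic: the largest temperature rise
found inside any sliding window of length ``L`` days whose *last* day falls
within the spring interval. "Rise" is, by default, the maximum of
``T[j] − T[i]`` over ordered day pairs ``i < j`` inside the window (an
endpoint-difference variant is available via ``rise="endpoints"``). The
annual STT values are then regressed against the peak summer egg count via
ordinary least squares, giving a model that can predict a future summer
peak from that spring's temperature record alone.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import DailySeries, SampleSeries

__all__ = [
    "SeasonSpec",
    "TriggerResult",
    "TriggerModel",
    "window_rise",
    "compute_stt",
    "peak_eggs",
    "fit_trigger_model",
    "predict_peak",
    "shannon_diversity",
    "resolve_interval",
]

MonthDay = tuple

FULL_YEAR = ((1, 1), (12, 31))


def _resolve_md(year: int, md: MonthDay, offset_days: int = 0) -> pd.Timestamp:
    """(month, day) -> Timestamp in `year`, clamping day to the month length.

    The clamp makes (2, 29) mean "end of February" in non-leap years.
    """
    month, day = md
    day = min(day, calendar.monthrange(year, month)[1])
    return pd.Timestamp(year, month, day) + pd.Timedelta(days=offset_days)


def resolve_interval(year: int, interval, start_offset: int = 0, end_offset: int = 0):
    """Resolve a ((month, day), (month, day)) pair within one calendar year."""
    (sm, sd), (em, ed) = interval
    return (_resolve_md(year, (sm, sd), start_offset), _resolve_md(year, (em, ed), end_offset))


@dataclass(frozen=True)
class SeasonSpec:
    """Season boundary dates as (month, day) pairs.

    Winter may span the year boundary: the winter attached to year ``y``
    runs from ``winter_start`` of ``y − 1`` through ``winter_end`` of ``y``
    (Feb 29 belongs to winter in leap years).
    """

    spring_start: MonthDay = (4, 1)
    spring_end: MonthDay = (6, 18)
    summer_start: MonthDay = (6, 1)
    summer_end: MonthDay = (8, 31)
    winter_start: MonthDay = (12, 1)
    winter_end: MonthDay = (2, 29)

    def spring(self, year: int, end_offset: int = 0):
        lo, hi = resolve_interval(year, (self.spring_start, self.spring_end), 0, end_offset)
        if hi < lo:
            raise ValueError(f"empty spring interval for {year} (offset {end_offset})")
        return lo, hi

    def summer(self, year: int, start_offset: int = 0):
        lo, hi = resolve_interval(year, (self.summer_start, self.summer_end), start_offset, 0)
        if hi < lo:
            raise ValueError(f"empty summer interval for {year} (offset {start_offset})")
        return lo, hi

    def winter(self, year: int):
        """Winter preceding year's summer: Dec of year−1 through Feb of year."""
        lo = _resolve_md(year - 1, self.winter_start)
        hi = _resolve_md(year, self.winter_end)
        return lo, hi


DEFAULT_SEASON = SeasonSpec()


@dataclass(frozen=True)
class TriggerResult:
    year: int
    stt: float
    window_length: int
    window_end: pd.Timestamp
    rise_start: pd.Timestamp
    rise_end: pd.Timestamp


@dataclass(frozen=True)
class TriggerModel:
    slope: float
    intercept: float
    rho: float
    n: int


def window_rise(values: Sequence[float]):
    """Largest rise max_{i<j}(v[j] − v[i]) with its (start, end) indices.

    If every ordered pair declines, the rise is reported as 0.0 and the
    indices are those of the least-declining pair. Ties break to the
    earliest start, then the shortest span.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError(f"window_rise needs at least 2 values, got {v.size}")
    runmin = np.minimum.accumulate(v)
    diffs = v[1:] - runmin[:-1]
    j = int(np.argmax(diffs)) + 1  # first max -> earliest start, shortest span
    i = int(np.argmax(v[:j] == runmin[j - 1]))  # earliest attaining index
    return max(float(diffs[j - 1]), 0.0), i, j


def rises_per_end(
    sst: DailySeries,
    first_end: pd.Timestamp,
    last_end: pd.Timestamp,
    L: int,
    min_coverage: float = 0.8,
    rise: str = "pairwise",
):
    """Windowed rise for every window end date in [first_end, last_end].

    Returns ``(ends, rises, starts_idx, ends_idx, cal)`` where ``rises[k]``
    is the best rise for the window of length L ending at ``ends[k]`` (NaN
    when fewer than ``min_coverage × L`` days are available) and the index
    arrays locate the achieving pair on the calendar ``cal``.
    """
    span_start = first_end - pd.Timedelta(days=L - 1)
    cal = pd.date_range(span_start, last_end, freq="D")
    dense = sst.data.reindex(cal).to_numpy()
    n_ends = (last_end - first_end).days + 1
    need = min_coverage * L - 1e-9
    rises = np.full(n_ends, np.nan)
    si = np.full(n_ends, -1, dtype=int)
    sj = np.full(n_ends, -1, dtype=int)
    for e in range(n_ends):
        window = dense[e : e + L]  # covers [end-L+1, end]
        avail = ~np.isnan(window)
        count = int(avail.sum())
        if count < need or count < 2:
            continue
        vals = window[avail]
        if rise == "endpoints":
            r = max(float(vals[-1] - vals[0]), 0.0)
            ii, jj = 0, vals.size - 1
        else:
            r, ii, jj = window_rise(vals)
        offs = np.flatnonzero(avail)
        rises[e] = r
        si[e] = e + offs[ii]
        sj[e] = e + offs[jj]
    ends = pd.date_range(first_end, last_end, freq="D")
    return ends, rises, si, sj, cal


def _best_rise_over_ends(
    sst: DailySeries,
    first_end: pd.Timestamp,
    last_end: pd.Timestamp,
    L: int,
    min_coverage: float,
    rise: str,
):
    """Max rise over windows of length L whose last day lies in [first_end, last_end].

    Returns (rise, window_end, rise_start_date, rise_end_date) or None when no
    window position has enough coverage. Ties break to the earliest end.
    """
    ends, rises, si, sj, cal = rises_per_end(sst, first_end, last_end, L, min_coverage, rise)
    if np.isnan(rises).all():
        return None
    k = int(np.nanargmax(rises))  # first max -> earliest window end
    return float(rises[k]), ends[k], cal[si[k]], cal[sj[k]]


def compute_stt(
    sst: DailySeries,
    year: int,
    L: int,
    season: SeasonSpec = DEFAULT_SEASON,
    *,
    spring_end_offset: int = 0,
    min_coverage: float = 0.8,
    rise: str = "pairwise",
) -> TriggerResult:
    """Spring temperature trigger for one year.

    Windows of length ``L`` slide in daily increments with their last day
    traversing the spring interval (both traversal endpoints inclusive);
    the STT is the maximum windowed rise found. Window positions with fewer
    than ``min_coverage × L`` available days are skipped; if every position
    is skipped the year is unusable and an error is raised.
    """
    if L < 2:
        raise ValueError(f"window length L must be >= 2, got {L}")
    if rise not in ("pairwise", "endpoints"):
        raise ValueError(f"unknown rise mode {rise!r}")
    lo, hi = season.spring(year, end_offset=spring_end_offset)
    best = _best_rise_over_ends(sst, lo, hi, L, min_coverage, rise)
    if best is None:
        raise ValueError(
            f"no window position with sufficient SST coverage in spring {year} "
            f"({lo.date()}..{hi.date()}, L={L})"
        )
    r, wend, rstart, rend = best
    return TriggerResult(year, r, L, wend, rstart, rend)


def peak_eggs(eggs: SampleSeries, year: int, interval=None, *, start_offset: int = 0):
    """Maximum observed egg count within a (month, day) interval of a year.

    Ties break to the earliest date. Errors when the interval holds no
    collection.
    """
    if interval is None:
        interval = (DEFAULT_SEASON.summer_start, DEFAULT_SEASON.summer_end)
    lo, hi = resolve_interval(year, interval, start_offset, 0)
    if hi < lo:
        raise ValueError(f"empty interval for {year} (offset {start_offset})")
    chunk = eggs.between(lo, hi)
    if chunk.empty:
        raise ValueError(
            f"no egg collections in {year} within {lo.date()}..{hi.date()}"
        )
    peak = float(chunk.max())
    date = chunk.index[int(np.argmax(chunk.to_numpy()))]
    return peak, date


def fit_trigger_model(stts: Sequence[float], peaks: Sequence[float]) -> TriggerModel:
    """OLS fit of peak eggs on STT plus their Pearson correlation."""
    x = np.asarray(stts, dtype=float)
    y = np.asarray(peaks, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("stts and peaks must be equal-length 1-D sequences")
    if x.size < 3:
        raise ValueError(f"need at least 3 years to fit, got {x.size}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in regression inputs")
    if np.ptp(x) == 0.0:
        raise ValueError("zero variance in STT values: slope and rho undefined")
    if np.ptp(y) == 0.0:
        raise ValueError("zero variance in peak values: rho undefined")
    fit = stats.linregress(x, y)
    return TriggerModel(float(fit.slope), float(fit.intercept), float(fit.rvalue), int(x.size))


def predict_peak(model: TriggerModel, stt: float) -> float:
    """Predicted peak eggs for a new year's STT (may be negative; reported as-is)."""
    if not np.isfinite(stt):
        raise ValueError("stt must be finite")
    return model.intercept + model.slope * float(stt)


def shannon_diversity(counts: Sequence[float]) -> float:
    """Shannon diversity H = −Σ p_i ln p_i (nats) over positive counts."""
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("counts must be nonnegative")
    c = c[c > 0]
    if c.size == 0:
        raise ValueError("at least one positive count required")
    return float(stats.entropy(c))
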