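"""Structural-sensitivity audits of the trigger→peak relationship.

Each scan re-runs the STT → peak-eggs correlation while varying one of the
non-fitted modelling choices — sliding-window width, spring/summer boundary
dates, the restriction of the trigger to spring, or the degree of SST
smoothing — plus two coarser checks (lagged daily cross-correlation and the
winter-mean vs egg-mean seasonal correlation) and a correlation matrix of
the derived annual variables. The scans quantify how much of an apparently
strong correlation is attributable to the freedom in these structural
choices: a maximum taken over a grid of configurations can only grow as the
grid grows, so scan maxima on null data measure the overfitting hazard.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import DailySeries, SampleSeries, moving_average
from .trigger import (
    DEFAULT_SEASON,
    FULL_YEAR,
    SeasonSpec,
    _best_rise_over_ends,
    compute_stt,
    peak_eggs,
    resolve_interval,
    rises_per_end,
)

__all__ = [
    "ScanResult",
    "window_width_scan",
    "boundary_scan",
    "anytime_trigger_scan",
    "smoothing_scan",
    "lagged_crosscorr",
    "seasonal_aggregate_corr",
    "annual_variable_matrix",
    "egg_years",
]

logger = logging.getLogger("springtrigger")

DEFAULT_WINTER = ((12, 1), (2, 29))
DEFAULT_SPRING_SUMMER = ((3, 1), (8, 31))


@dataclass(frozen=True)
class ScanResult:
    """Tidy scan table: one row per grid point with columns
    ``<axis columns...>, rho, n, valid``. Grid points with fewer than 3
    usable years are marked invalid (rho = NaN), never silently dropped."""

    table: pd.DataFrame
    axes: tuple

    def rho_at(self, **coords) -> float:
        m = np.ones(len(self.table), dtype=bool)
        for k, v in coords.items():
            m &= self.table[k].to_numpy() == v
        sub = self.table[m]
        if len(sub) != 1:
            raise KeyError(f"grid point {coords} matches {len(sub)} rows")
        return float(sub["rho"].iloc[0])

    @property
    def max_abs_rho(self) -> float:
        valid = self.table[self.table["valid"]]
        if valid.empty:
            raise ValueError("no valid grid points")
        return float(valid["rho"].abs().max())


def egg_years(eggs: SampleSeries) -> list:
    return sorted(set(eggs.dates.year))


def _pearson(x: np.ndarray, y: np.ndarray):
    """(rho, n) with rho = NaN when undefined (n < 3 or zero variance)."""
    n = len(x)
    if n < 3:
        return float("nan"), n
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(xc @ xc)
    sy = np.sqrt(yc @ yc)
    if sx == 0.0 or sy == 0.0:
        return float("nan"), n
    return float(np.clip(xc @ yc / (sx * sy), -1.0, 1.0)), n


def _annual_stts(sst, years, L, season, spring_end_offset=0, rise="pairwise"):
    out = {}
    for y in years:
        try:
            out[y] = compute_stt(
                sst, y, L, season, spring_end_offset=spring_end_offset, rise=rise
            ).stt
        except ValueError:
            continue
    return out


def _annual_peaks(eggs, years, season, summer_start_offset=0):
    out = {}
    interval = (season.summer_start, season.summer_end)
    for y in years:
        try:
            out[y] = peak_eggs(eggs, y, interval, start_offset=summer_start_offset)[0]
        except ValueError:
            continue
    return out


def _corr_from_maps(stts: dict, peaks: dict):
    common = sorted(set(stts) & set(peaks))
    x = np.array([stts[y] for y in common])
    y = np.array([peaks[y] for y in common])
    return _pearson(x, y)


def window_width_scan(
    sst: DailySeries,
    eggs: SampleSeries,
    L_grid: Sequence[int],
    season: SeasonSpec = DEFAULT_SEASON,
) -> ScanResult:
    """ρ(STT, peak summer eggs) across years, for each sliding-window width L."""
    years = egg_years(eggs)
    peaks = _annual_peaks(eggs, years, season)
    rows = []
    for L in L_grid:
        try:
            stts = _annual_stts(sst, years, int(L), season)
            rho, n = _corr_from_maps(stts, peaks)
        except ValueError:
            rho, n = float("nan"), 0
        rows.append({"L": int(L), "rho": rho, "n": n, "valid": np.isfinite(rho)})
    return ScanResult(pd.DataFrame(rows), axes=("L",))


def boundary_scan(
    sst: DailySeries,
    eggs: SampleSeries,
    spring_end_offsets: Sequence[int],
    summer_start_offsets: Sequence[int],
    L: int,
    season: SeasonSpec = DEFAULT_SEASON,
) -> ScanResult:
    """2-D ρ surface over day shifts of the spring-end and summer-start dates.

    The (0, 0) cell reproduces the unshifted analysis exactly. Shifts that
    empty an interval yield invalid cells.
    """
    years = egg_years(eggs)
    ds_list = [int(d) for d in spring_end_offsets]
    dss_list = [int(d) for d in summer_start_offsets]
    max_ds = max(ds_list)

    # Per year, the per-window-end rises over the widest traversal are
    # computed once; the STT at each spring-end offset is then a running
    # maximum over window ends — identical to calling compute_stt per cell.
    stt_mat = np.full((len(ds_list), len(years)), np.nan)
    for yi, year in enumerate(years):
        try:
            lo, _ = season.spring(year)
            hi = season.spring(year, end_offset=max(max_ds, 0))[1]
        except ValueError:
            continue
        try:
            _, rises, _, _, _ = rises_per_end(sst, lo, hi, L)
        except Exception:
            continue
        cummax = np.fmax.accumulate(np.where(np.isnan(rises), -np.inf, rises))
        full_span = (hi - lo).days  # index of the last end at offset 0 + max_ds
        for di, ds in enumerate(ds_list):
            try:
                end = season.spring(year, end_offset=ds)[1]
            except ValueError:
                continue  # empty shifted interval -> invalid
            k = (end - lo).days
            if k < 0 or k > full_span:
                continue
            v = cummax[k]
            if np.isfinite(v):
                stt_mat[di, yi] = v

    peak_mat = np.full((len(dss_list), len(years)), np.nan)
    for si_, dss in enumerate(dss_list):
        pk = _annual_peaks(eggs, years, season, summer_start_offset=dss)
        for yi, year in enumerate(years):
            if year in pk:
                peak_mat[si_, yi] = pk[year]

    rows = []
    for di, ds in enumerate(ds_list):
        for si_, dss in enumerate(dss_list):
            x = stt_mat[di]
            y = peak_mat[si_]
            ok = np.isfinite(x) & np.isfinite(y)
            rho, n = _pearson(x[ok], y[ok])
            rows.append(
                {
                    "spring_end_offset": ds,
                    "summer_start_offset": dss,
                    "rho": rho,
                    "n": n,
                    "valid": np.isfinite(rho),
                }
            )
    return ScanResult(pd.DataFrame(rows), axes=("spring_end_offset", "summer_start_offset"))


def anytime_trigger_scan(sst: DailySeries, eggs: SampleSeries, L: int):
    """Trigger allowed at any time before the *annual* peak, vs that peak.

    Per year the annual peak is the maximum collection between Jan 1 and
    Dec 31; the trigger is the largest windowed rise with the window's last
    day ranging from Jan 28 to the day before the peak. Years whose peak
    falls on or before Jan 28 are excluded with a warning. Returns
    ``(rho, records)`` where records has one row per usable year.
    """
    years = egg_years(eggs)
    recs = []
    for y in years:
        try:
            peak, pdate = peak_eggs(eggs, y, FULL_YEAR)
        except ValueError:
            continue
        first_end = pd.Timestamp(y, 1, 28)
        last_end = pdate - pd.Timedelta(days=1)
        if last_end < first_end:
            logger.warning("year %d: annual peak %s precedes Jan 29; excluded", y, pdate.date())
            continue
        best = _best_rise_over_ends(sst, first_end, last_end, int(L), 0.8, "pairwise")
        if best is None:
            logger.warning("year %d: no SST coverage for any-time trigger; excluded", y)
            continue
        recs.append({"year": y, "trigger": best[0], "peak": peak, "peak_date": pdate})
    records = pd.DataFrame(recs)
    if len(records) < 3:
        raise ValueError(f"need >= 3 usable years for rho, got {len(records)}")
    rho, _ = _pearson(records["trigger"].to_numpy(), records["peak"].to_numpy())
    return rho, records


def smoothing_scan(
    sst: DailySeries,
    eggs: SampleSeries,
    widths: Sequence[int],
    L: int,
    season: SeasonSpec = DEFAULT_SEASON,
) -> ScanResult:
    """ρ(STT, peak summer eggs) as SST is smoothed from daily to monthly."""
    years = egg_years(eggs)
    peaks = _annual_peaks(eggs, years, season)
    rows = []
    for w in widths:
        sm = moving_average(sst, int(w))
        stts = _annual_stts(sm, years, L, season)
        rho, n = _corr_from_maps(stts, peaks)
        rows.append({"width": int(w), "rho": rho, "n": n, "valid": np.isfinite(rho)})
    return ScanResult(pd.DataFrame(rows), axes=("width",))


def lagged_crosscorr(
    sst: DailySeries,
    eggs: SampleSeries,
    delays: Sequence[int],
    winter=DEFAULT_WINTER,
    match_tolerance: int = 2,
) -> ScanResult:
    """Daily winter SST vs the egg collection nearest t + delay.

    For each delay d, each winter-day temperature at date t is paired with
    the collection nearest to t + d within ±match_tolerance days (ties to
    the earlier collection); unpaired days are dropped. Delays with fewer
    than 3 pairs are invalid.
    """
    delays = [int(d) for d in delays]
    if any(d < 0 for d in delays):
        raise ValueError("delays must be nonnegative")
    years = sorted(set(sst.dates.year))
    wdates, wvals = [], []
    for y in years:
        lo = pd.Timestamp(y - 1, winter[0][0], winter[0][1])
        hi = resolve_interval(y, winter)[1]
        chunk = sst.between(lo, hi)
        wdates.append(chunk.index)
        wvals.append(chunk.to_numpy())
    if not wdates:
        raise ValueError("no winter SST days available")
    wdates = pd.DatetimeIndex(np.concatenate([d.values for d in wdates])).unique().sort_values()
    wvals = sst.data.loc[wdates].to_numpy()

    edays = eggs.dates.values.astype("datetime64[D]").astype(np.int64)
    evals = eggs.values
    tdays = wdates.values.astype("datetime64[D]").astype(np.int64)
    rows = []
    for d in delays:
        target = tdays + d
        pos = np.searchsorted(edays, target)
        left = np.clip(pos - 1, 0, len(edays) - 1)
        right = np.clip(pos, 0, len(edays) - 1)
        dl = np.abs(target - edays[left])
        dr = np.abs(edays[right] - target)
        pick = np.where(dl <= dr, left, right)  # tie -> earlier collection
        dist = np.minimum(dl, dr)
        ok = dist <= match_tolerance
        rho, n = _pearson(wvals[ok], evals[pick[ok]])
        rows.append({"delay": d, "rho": rho, "n": n, "valid": np.isfinite(rho)})
    return ScanResult(pd.DataFrame(rows), axes=("delay",))


def seasonal_aggregate_corr(
    sst: DailySeries,
    eggs: SampleSeries,
    winter=DEFAULT_WINTER,
    spring_summer=DEFAULT_SPRING_SUMMER,
):
    """Mean winter SST vs mean spring–summer egg abundance, across years.

    Winter of year y runs from December of y − 1 through February of y;
    the egg average covers March–August of y. Years missing either season
    are excluded with a warning; fewer than 3 usable years is an error.
    Returns ``(rho, per_year)``.
    """
    years = egg_years(eggs)
    recs = []
    for y in years:
        wlo = pd.Timestamp(y - 1, winter[0][0], winter[0][1])
        whi = resolve_interval(y, winter)[1]
        wchunk = sst.between(wlo, whi)
        elo, ehi = resolve_interval(y, spring_summer)
        echunk = eggs.between(elo, ehi)
        if wchunk.empty or echunk.empty:
            logger.warning("year %d: missing winter SST or spring-summer eggs; excluded", y)
            continue
        recs.append(
            {"year": y, "winter_sst": float(wchunk.mean()), "egg_mean": float(echunk.mean())}
        )
    per_year = pd.DataFrame(recs)
    if len(per_year) < 3:
        raise ValueError(f"need >= 3 usable years, got {len(per_year)}")
    x = per_year["winter_sst"].to_numpy()
    y_ = per_year["egg_mean"].to_numpy()
    if np.ptp(x) == 0.0 or np.ptp(y_) == 0.0:
        raise ValueError("zero variance in a seasonal aggregate: rho undefined")
    rho, _ = _pearson(x, y_)
    return rho, per_year


ANNUAL_VARIABLES = ("stt", "peak_summer_eggs", "mean_summer_eggs", "mean_winter_sst")


def annual_variable_matrix(
    sst: DailySeries,
    eggs: SampleSeries,
    season: SeasonSpec = DEFAULT_SEASON,
    L: int = 28,
) -> pd.DataFrame:
    """Pairwise Pearson ρ of the four derived annual variables.

    Rows/columns: STT, peak summer eggs, mean summer eggs, mean winter SST.
    Symmetric with unit diagonal; a zero-variance variable gets NaN in its
    off-diagonal row/column (marked invalid).
    """
    years = egg_years(eggs)
    recs = []
    for y in years:
        try:
            stt = compute_stt(sst, y, L, season).stt
            peak = peak_eggs(eggs, y, (season.summer_start, season.summer_end))[0]
        except ValueError:
            continue
        slo, shi = season.summer(y)
        summer_eggs = eggs.between(slo, shi)
        wlo, whi = season.winter(y)
        winter_sst = sst.between(wlo, whi)
        if summer_eggs.empty or winter_sst.empty:
            continue
        recs.append(
            {
                "stt": stt,
                "peak_summer_eggs": peak,
                "mean_summer_eggs": float(summer_eggs.mean()),
                "mean_winter_sst": float(winter_sst.mean()),
            }
        )
    df = pd.DataFrame(recs, columns=list(ANNUAL_VARIABLES))
    if len(df) < 3:
        raise ValueError(f"need >= 3 complete years, got {len(df)}")
    k = len(ANNUAL_VARIABLES)
    mat = np.eye(k)
    vals = df.to_numpy()
    for i in range(k):
        for j in range(i + 1, k):
            rho, _ = _pearson(vals[:, i], vals[:, j])
            mat[i, j] = mat[j, i] = rho
    return pd.DataFrame(mat, index=list(ANNUAL_VARIABLES), columns=list(ANNUAL_VARIABLES))
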