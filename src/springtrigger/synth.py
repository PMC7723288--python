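"""Seeded synthetic SST / egg-abundance study generator.

Emulates the statistical structure of a multi-year pier monitoring record:

* SST: an annual cosine (period 365 d, warmest mid-August) plus AR(1)
  day-to-day noise, plus one discrete spring warming event per year — a
  triangular bump that ramps up linearly over ``event_duration`` days and
  relaxes back over the same duration, so the largest windowed rise equals
  the injected magnitude.
* Eggs: a latent daily curve (low baseline + one Gaussian-shaped summer
  peak per year) observed at irregular tow dates 2–5 days apart. In coupled
  mode the peak height is a linear function of that year's true event
  magnitude; under the null it is drawn independently of the events.

One integer seed governs every draw; identical parameters and seed give
bit-identical output. The per-year ground truth (event magnitude and day,
latent peak height and day) is returned alongside the observables so that
recovery can be tested.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal

from .io import DailySeries, SampleSeries

__all__ = ["SyntheticParams", "generate_sst", "generate_eggs", "generate_study"]

_SST_STREAM, _EVENT_STREAM, _EGG_STREAM = 0, 1, 2


@dataclass(frozen=True)
class SyntheticParams:
    """Study conditions for the synthetic generator.

    ``event_magnitudes`` is either a (low, high) pair — per-year magnitudes
    are drawn uniformly from it — or an explicit per-year sequence.
    ``event_day_window`` / ``peak_day_window`` are day-of-year intervals;
    the event window must precede the peak window.
    """

    n_years: int = 7
    start_year: int = 2013
    sst_mean: float = 17.5          # °C
    sst_amplitude: float = 4.0      # °C, seasonal cosine half-range
    sst_peak_doy: int = 225         # warmest day of year (mid-August)
    ar_coeff: float = 0.9           # AR(1) coefficient of daily residuals
    ar_sd: float = 0.17             # °C, AR(1) innovation sd (stationary sd ~0.39)
    event_day_window: Tuple[int, int] = (75, 151)   # day-of-year of ramp start
    event_magnitudes: Sequence[float] = (0.75, 5.25)  # °C
    event_duration: int = 10        # days of linear ramp-up (and relaxation)
    egg_baseline: float = 10.0      # eggs/tow
    coupling_slope: float = 150.0   # eggs/tow per °C of event magnitude
    coupling_intercept: float = 200.0
    peak_noise_sd: float = 30.0     # eggs/tow
    peak_day_window: Tuple[int, int] = (152, 240)   # day-of-year of summer peak
    peak_width: float = 12.0        # days, Gaussian sd of the peak
    sampling_gap_range: Tuple[int, int] = (2, 5)    # days between tows
    tow_noise_cv: float = 0.10      # per-tow lognormal patchiness (CV, mean 1)
    observation: str = "round"      # "round" | "poisson"
    null_model: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_years < 1:
            raise ValueError("n_years must be >= 1")
        for name in ("sst_amplitude", "ar_sd", "event_duration", "egg_baseline",
                     "peak_noise_sd", "peak_width", "tow_noise_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.ar_coeff < 1.0:
            raise ValueError("ar_coeff must lie in [0, 1)")
        gmin, gmax = self.sampling_gap_range
        if not (1 <= gmin <= gmax):
            raise ValueError("sampling_gap_range must satisfy 1 <= min <= max")
        if self.event_day_window[0] > self.event_day_window[1]:
            raise ValueError("event_day_window must be a nonempty interval")
        if self.peak_day_window[0] > self.peak_day_window[1]:
            raise ValueError("peak_day_window must be a nonempty interval")
        if self.event_day_window[1] >= self.peak_day_window[0]:
            raise ValueError("event_day_window must precede peak_day_window")
        if self.observation not in ("round", "poisson"):
            raise ValueError("observation must be 'round' or 'poisson'")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), stream]))


def _years(params: SyntheticParams) -> np.ndarray:
    return np.arange(params.start_year, params.start_year + params.n_years)


def _calendar(params: SyntheticParams) -> pd.DatetimeIndex:
    return pd.date_range(
        f"{params.start_year}-01-01",
        f"{params.start_year + params.n_years - 1}-12-31",
        freq="D",
    )


def _draw_events(params: SyntheticParams):
    """Per-year true event magnitudes (°C) and ramp-start days of year.

    Drawn from a dedicated seed stream so that generate_sst and
    generate_eggs agree on the truth without sharing state.
    """
    rng = params.rng(_EVENT_STREAM)
    mags = np.asarray(params.event_magnitudes, dtype=float)
    if mags.size == 2 and params.n_years != 2:
        lo, hi = mags
        mags = rng.uniform(lo, hi, size=params.n_years)
    elif mags.size == params.n_years:
        rng.uniform(0, 1, size=params.n_years)  # keep stream alignment
    else:
        raise ValueError(
            "event_magnitudes must be (low, high) bounds or one value per year"
        )
    lo_d, hi_d = params.event_day_window
    days = rng.integers(lo_d, hi_d + 1, size=params.n_years)
    return mags, days


def generate_sst(params: SyntheticParams) -> DailySeries:
    """Daily SST: seasonal cosine + AR(1) noise + one spring warming bump per year."""
    cal = _calendar(params)
    doy = cal.dayofyear.to_numpy()
    base = params.sst_mean + params.sst_amplitude * np.cos(
        2.0 * np.pi * (doy - params.sst_peak_doy) / 365.0
    )

    rng = params.rng(_SST_STREAM)
    n = len(cal)
    noise = np.zeros(n)
    if params.ar_sd > 0:
        innov = rng.normal(0.0, params.ar_sd, size=n)
        a = params.ar_coeff
        innov[0] /= np.sqrt(1.0 - a * a)  # stationary start
        noise = signal.lfilter([1.0], [1.0, -a], innov)

    mags, start_doys = _draw_events(params)
    bump = np.zeros(n)
    years = cal.year.to_numpy()
    dur = int(params.event_duration)
    for y, m, d0 in zip(_years(params), mags, start_doys):
        year_start = np.searchsorted(years, y)
        s = year_start + int(d0) - 1  # ramp start index
        up = np.arange(dur + 1) / max(dur, 1)
        down = up[::-1][1:]
        shape = np.concatenate([up, down]) * m
        e = min(s + shape.size, n)
        bump[s:e] += shape[: e - s]
    return DailySeries(pd.Series(base + noise + bump, index=cal), label="sst")


def _latent_curve(params: SyntheticParams):
    """Latent daily egg curve plus per-year truth (heights, peak days)."""
    cal = _calendar(params)
    mags, start_doys = _draw_events(params)
    rng = params.rng(_EGG_STREAM)

    if params.null_model:
        # same marginal spread as the true magnitudes, but independent of them
        lo, hi = float(np.min(mags)), float(np.max(mags))
        if hi <= lo:
            hi = lo + 1.0
        drive = rng.uniform(lo, hi, size=params.n_years)
    else:
        drive = mags
    noise = (
        rng.normal(0.0, params.peak_noise_sd, size=params.n_years)
        if params.peak_noise_sd > 0
        else np.zeros(params.n_years)
    )
    heights = np.maximum(
        params.coupling_intercept + params.coupling_slope * drive + noise, 0.0
    )
    lo_d, hi_d = params.peak_day_window
    peak_doys = rng.integers(lo_d, hi_d + 1, size=params.n_years)

    t = np.arange(len(cal), dtype=float)
    years = cal.year.to_numpy()
    curve = np.full(len(cal), params.egg_baseline, dtype=float)
    peak_idx = np.empty(params.n_years, dtype=int)
    for i, y in enumerate(_years(params)):
        p = np.searchsorted(years, y) + int(peak_doys[i]) - 1
        peak_idx[i] = p
        curve += heights[i] * np.exp(-0.5 * ((t - p) / params.peak_width) ** 2)
    truth = pd.DataFrame(
        {
            "year": _years(params),
            "event_magnitude": mags,
            "event_start_doy": start_doys,
            "peak_height": params.egg_baseline + heights,
            "peak_doy": peak_doys,
        }
    )
    return cal, curve, truth, rng


def generate_eggs(sst: DailySeries, params: SyntheticParams) -> SampleSeries:
    """Irregular tow observations of the latent egg curve.

    ``sst`` must span the parameterised years (the latent curve is built on
    the same calendar). Gaps between tows are uniform integers from
    ``sampling_gap_range``; counts are the latent curve rounded to
    nonnegative integers (or Poisson-sampled when ``observation='poisson'``).
    """
    cal, curve, _, rng = _latent_curve(params)
    if sst.dates[0] > cal[0] or sst.dates[-1] < cal[-1]:
        raise ValueError("sst does not span the parameterised years")
    gmin, gmax = params.sampling_gap_range
    idx = [int(rng.integers(0, gmax))]  # first tow within the first gap
    while True:
        nxt = idx[-1] + int(rng.integers(gmin, gmax + 1))
        if nxt >= len(cal):
            break
        idx.append(nxt)
    idx = np.asarray(idx)
    latent = curve[idx]
    if params.tow_noise_cv > 0:
        # mean-one lognormal patchiness: adjacent tows of the same latent
        # abundance still differ, as real plankton tows do
        sig = np.sqrt(np.log1p(params.tow_noise_cv**2))
        latent = latent * rng.lognormal(-0.5 * sig * sig, sig, size=latent.size)
    if params.observation == "poisson":
        counts = rng.poisson(latent).astype(float)
    else:
        counts = np.maximum(np.round(latent), 0.0)
    return SampleSeries(pd.Series(counts, index=cal[idx]), label="eggs")


def generate_study(params: SyntheticParams):
    """(sst, eggs, truth): the paired study plus per-year ground truth."""
    sst = generate_sst(params)
    eggs = generate_eggs(sst, params)
    _, _, truth, _ = _latent_curve(params)
    return sst, eggs, truth
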