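"""Empirical dynamic modeling on irregularly sampled series.

State space is reconstructed from lagged copies of the egg-abundance
observable: a row exists for every collection date t that also has
collections within a tolerance of the nominal lags (defaults 7 and 14 days,
±1 day) and a covariate (daily SST) value at t. Three analyses operate on
that embedding:

* ``smap_forecast`` / ``theta_scan`` — locally weighted linear (S-map)
  leave-one-out forecasting of the own-time egg value from the lagged
  coordinates; if forecast skill improves as the locality parameter θ grows
  beyond 0, the dynamics are state-dependent (nonlinear).
* ``ccm`` — convergent cross mapping: the covariate (temperature) is
  predicted from the egg-state neighbors, using random libraries of growing
  size whose candidates are restricted to calendar-proximate points so that
  shared seasonality cannot masquerade as cross-map skill. Rising skill
  with library size indicates a dynamic causal effect of temperature on
  egg abundance.
* ``convergence_summary`` — the rise-and-slope test applied to a CCM curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .io import DailySeries, SampleSeries

__all__ = [
    "Embedding",
    "SmapResult",
    "CCMResult",
    "ConvergenceSummary",
    "build_embedding",
    "smap_forecast",
    "theta_scan",
    "ccm",
    "convergence_summary",
]

DEFAULT_LAGS = (7, 14)
DEFAULT_LAG_TOLERANCE = 1


@dataclass(frozen=True)
class Embedding:
    """Lag-coordinate rows from irregular collections, with a covariate.

    ``table`` columns: ``target_date``, ``x_lag0`` (own-time value),
    ``x_lag<τ>`` for each nominal lag τ, and ``y`` (covariate at the target
    date). Every lag coordinate is an actual collection within the stated
    tolerance of its nominal lag. Rows are sorted by date, no duplicates.
    """

    table: pd.DataFrame
    lags: Tuple[int, ...]
    tolerance: int

    @property
    def E(self) -> int:
        return 1 + len(self.lags)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.table["target_date"])

    def state_matrix(self) -> np.ndarray:
        """All E lag coordinates (own-time first) as an (n, E) array."""
        cols = ["x_lag0"] + [f"x_lag{t}" for t in self.lags]
        return self.table[cols].to_numpy(dtype=float)

    def predictor_matrix(self) -> np.ndarray:
        """Strictly lagged coordinates, (n, E−1)."""
        cols = [f"x_lag{t}" for t in self.lags]
        return self.table[cols].to_numpy(dtype=float)

    @property
    def targets(self) -> np.ndarray:
        return self.table["x_lag0"].to_numpy(dtype=float)

    @property
    def covariate(self) -> np.ndarray:
        return self.table["y"].to_numpy(dtype=float)


@dataclass(frozen=True)
class SmapResult:
    table: pd.DataFrame  # columns theta, rho, n
    nonlinear: bool
    threshold: float

    def rho(self, theta: float) -> float:
        m = self.table["theta"].to_numpy() == theta
        if m.sum() != 1:
            raise KeyError(f"theta {theta} not on the scan grid")
        return float(self.table["rho"].to_numpy()[m][0])


@dataclass(frozen=True)
class CCMResult:
    table: pd.DataFrame  # columns library_size, mean_rho, sd_rho, n_targets
    n_draws: int
    seed: int


@dataclass(frozen=True)
class ConvergenceSummary:
    rho_at_max: float
    slope: float
    converged: bool


def _match_lag(edays: np.ndarray, target_day: int, tol: int) -> Optional[int]:
    """Index of the collection nearest `target_day` within ±tol (tie -> earlier)."""
    pos = int(np.searchsorted(edays, target_day))
    best, bestd = None, None
    for cand in (pos - 1, pos):
        if 0 <= cand < len(edays):
            d = abs(int(edays[cand]) - target_day)
            if d <= tol and (bestd is None or d < bestd):
                best, bestd = cand, d
    return best


def build_embedding(
    eggs: SampleSeries,
    covariate: DailySeries,
    lags: Sequence[int] = DEFAULT_LAGS,
    tolerance: int = DEFAULT_LAG_TOLERANCE,
) -> Embedding:
    """Delay embedding of the egg series co-registered with a daily covariate.

    A row is produced for each collection date t such that (a) the
    covariate has a value at t and (b) for every nominal lag τ a collection
    exists with date in [t−τ−tol, t−τ+tol]; the collection nearest the
    nominal lag is used (ties to the earlier one).
    """
    lags = tuple(int(t) for t in lags)
    if tolerance < 0:
        raise ValueError("lag tolerance must be >= 0")
    if len(lags) == 0 or any(t <= 0 for t in lags):
        raise ValueError("nominal lags must be positive")
    edays = eggs.dates.values.astype("datetime64[D]").astype(np.int64)
    evals = eggs.values
    cov = covariate.data
    rows = []
    fail_counts = {t: 0 for t in lags}
    fail_cov = 0
    for i, t0 in enumerate(edays):
        date = eggs.dates[i]
        if date not in cov.index:
            fail_cov += 1
            continue
        coords = {}
        ok = True
        for tau in lags:
            j = _match_lag(edays, int(t0) - tau, tolerance)
            if j is None:
                fail_counts[tau] += 1
                ok = False
                break
            coords[f"x_lag{tau}"] = evals[j]
        if not ok:
            continue
        row = {"target_date": date, "x_lag0": evals[i]}
        row.update(coords)
        row["y"] = float(cov.loc[date])
        rows.append(row)
    if not rows:
        raise ValueError(
            f"empty embedding from {len(edays)} candidate dates "
            f"(no covariate: {fail_cov}; lag failures: {fail_counts})"
        )
    cols = ["target_date", "x_lag0"] + [f"x_lag{t}" for t in lags] + ["y"]
    table = pd.DataFrame(rows, columns=cols)
    return Embedding(table, lags, int(tolerance))


def _loo_masks(days: np.ndarray, exclusion: int):
    """For each row, boolean mask of rows outside the exclusion radius."""
    diff = np.abs(days[:, None] - days[None, :])
    return diff > exclusion


def smap_forecast(embedding: Embedding, theta: float, exclusion: int = 0):
    """Leave-one-out S-map forecast skill at one θ.

    For each target row, all rows within ``exclusion`` days are left out
    (``exclusion=0`` leaves out only the target itself); the remaining rows
    are weighted by ``w_i = exp(−θ d_i / d̄)`` with d_i the Euclidean
    distance in lagged-coordinate space and d̄ the mean distance to the
    target, and a weighted linear map (with intercept) from the lagged
    coordinates to the own-time egg value is solved by a rank-revealing
    least-squares decomposition. Returns ``(rho, predictions)`` where rho is
    the Pearson correlation of predictions with observations.
    """
    if theta < 0:
        raise ValueError("theta must be >= 0")
    n = len(embedding)
    if n < embedding.E + 2:
        raise ValueError(f"need at least E+2={embedding.E + 2} rows, got {n}")
    Xp = embedding.predictor_matrix()
    z = embedding.targets
    days = embedding.dates.values.astype("datetime64[D]").astype(np.int64)
    masks = _loo_masks(days, int(exclusion))
    preds = np.empty(n)
    for i in range(n):
        m = masks[i]
        if m.sum() < Xp.shape[1] + 1:
            raise ValueError(f"too few training rows for target {i} after exclusion")
        d = np.linalg.norm(Xp[m] - Xp[i], axis=1)
        dbar = d.mean()
        if dbar == 0.0:
            raise ValueError("degenerate embedding: all training states identical to target")
        w = np.exp(-theta * d / dbar)
        sw = np.sqrt(w)
        A = np.column_stack([np.ones(m.sum()), Xp[m]]) * sw[:, None]
        b = z[m] * sw
        coef, *_ = np.linalg.lstsq(A, b, rcond=None)
        preds[i] = coef[0] + Xp[i] @ coef[1:]
    if np.ptp(z) == 0.0 or np.ptp(preds) == 0.0:
        rho = float("nan")
    else:
        rho = float(stats.pearsonr(preds, z).statistic)
    out = pd.DataFrame(
        {"target_date": embedding.dates, "observed": z, "predicted": preds}
    )
    return rho, out


def theta_scan(
    embedding: Embedding,
    thetas: Sequence[float],
    exclusion: int = 0,
    nonlinear_threshold: float = 0.02,
) -> SmapResult:
    """S-map forecast skill across a θ grid; flags nonlinearity.

    The grid must contain θ = 0 (the global-linear limit); the series is
    flagged nonlinear when max ρ(θ) − ρ(0) exceeds the threshold.
    """
    thetas = [float(t) for t in thetas]
    if 0.0 not in thetas:
        raise ValueError("theta grid must contain 0")
    rows = []
    for t in thetas:
        rho, preds = smap_forecast(embedding, t, exclusion)
        if not np.isfinite(rho):
            raise ValueError(
                f"forecast skill undefined at theta={t} "
                "(constant observations or predictions)"
            )
        rows.append({"theta": t, "rho": rho, "n": len(preds)})
    table = pd.DataFrame(rows)
    rho0 = float(table.loc[table["theta"] == 0.0, "rho"].iloc[0])
    nonlinear = bool(table["rho"].max() - rho0 > nonlinear_threshold)
    return SmapResult(table, nonlinear, nonlinear_threshold)


def _candidate_pools(days: np.ndarray, proximity: int, mode: str):
    """Per-target index arrays of rows within the calendar-proximity limit."""
    if mode == "absolute":
        diff = np.abs(days[:, None] - days[None, :])
    elif mode == "day-of-year":
        doy = days % 365
        d = np.abs(doy[:, None] - doy[None, :])
        diff = np.minimum(d, 365 - d)
    else:
        raise ValueError(f"unknown proximity mode {mode!r}")
    np.fill_diagonal(diff, proximity + 1)  # a target is never its own candidate
    return [np.flatnonzero(diff[i] <= proximity) for i in range(len(days))]


def ccm(
    embedding: Embedding,
    library_sizes: Sequence[int] = tuple(range(10, 85, 5)),
    k: int = 4,
    proximity: int = 90,
    n_draws: int = 50,
    seed: int = 0,
    proximity_mode: str = "absolute",
    weighting: str = "exponential",
) -> CCMResult:
    """Cross-map the covariate from random libraries of embedded egg states.

    For each target row the candidate pool is every other row within
    ``proximity`` calendar days. Per draw, a library of the given size is
    sampled uniformly without replacement from each pool (targets with
    pools smaller than the library are skipped); the k nearest library rows
    in lag-coordinate space predict the target's covariate by the
    exponentially weighted average ``u_i = exp(−d_i/d_1)`` (equal weights
    when the nearest distance is 0, or with ``weighting='uniform'``). The
    per-draw skill is the Pearson correlation of predicted vs observed
    covariate over all usable targets; mean and sd over draws are reported
    per library size. Fully reproducible given ``seed``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if weighting not in ("exponential", "uniform"):
        raise ValueError(f"unknown weighting {weighting!r}")
    sizes = sorted(int(s) for s in library_sizes)
    if len(sizes) != len(set(sizes)):
        raise ValueError("library sizes must be distinct")
    coords = embedding.state_matrix()
    yv = embedding.covariate
    days = embedding.dates.values.astype("datetime64[D]").astype(np.int64)
    n = len(embedding)
    pools = _candidate_pools(days, int(proximity), proximity_mode)
    pool_sizes = np.array([p.size for p in pools])
    if (pool_sizes < k).all():
        raise ValueError(
            f"every candidate pool is smaller than k={k}; "
            f"largest pool has {int(pool_sizes.max())} points"
        )
    # pairwise distances in full lag-coordinate space
    sq = np.einsum("ij,ij->i", coords, coords)
    D2 = sq[:, None] + sq[None, :] - 2.0 * (coords @ coords.T)
    D = np.sqrt(np.maximum(D2, 0.0))

    rng = np.random.default_rng(seed)
    rows = []
    for s in sizes:
        eligible = np.flatnonzero(pool_sizes >= s)
        if eligible.size < 3:
            rows.append(
                {"library_size": s, "mean_rho": float("nan"), "sd_rho": float("nan"),
                 "n_targets": int(eligible.size)}
            )
            continue
        kk = min(k, s)
        draw_rhos = np.empty(n_draws)
        libs = np.empty((eligible.size, s), dtype=int)
        for dr in range(n_draws):
            for r, i in enumerate(eligible):
                libs[r] = rng.choice(pools[i], size=s, replace=False)
            dmat = D[eligible[:, None], libs]
            near = np.argpartition(dmat, kk - 1, axis=1)[:, :kk]
            dnear = np.take_along_axis(dmat, near, axis=1)
            order = np.argsort(dnear, axis=1)
            dnear = np.take_along_axis(dnear, order, axis=1)
            inear = np.take_along_axis(near, order, axis=1)
            nbr = np.take_along_axis(libs, inear, axis=1)
            if weighting == "uniform":
                u = np.ones_like(dnear)
            else:
                d1 = dnear[:, :1]
                with np.errstate(divide="ignore", invalid="ignore"):
                    u = np.exp(-dnear / d1)
                u[np.broadcast_to(d1 == 0.0, u.shape)] = 1.0
            pred = (u * yv[nbr]).sum(axis=1) / u.sum(axis=1)
            obs = yv[eligible]
            if np.ptp(obs) == 0.0 or np.ptp(pred) == 0.0:
                draw_rhos[dr] = float("nan")
            else:
                draw_rhos[dr] = stats.pearsonr(pred, obs).statistic
        rows.append(
            {
                "library_size": s,
                "mean_rho": float(np.nanmean(draw_rhos)),
                "sd_rho": float(np.nanstd(draw_rhos, ddof=1)) if n_draws > 1 else 0.0,
                "n_targets": int(eligible.size),
            }
        )
    return CCMResult(pd.DataFrame(rows), int(n_draws), int(seed))


def convergence_summary(result: CCMResult, margin: float = 0.1) -> ConvergenceSummary:
    """Convergence test: skill must rise from the smallest to the largest library.

    Converged when mean ρ at the largest library exceeds mean ρ at the
    smallest by at least ``margin`` and the linear trend of ρ vs library
    size is positive.
    """
    t = result.table[result.table["mean_rho"].notna()]
    if len(t) < 3:
        raise ValueError("need >= 3 library sizes with defined skill")
    sizes = t["library_size"].to_numpy(dtype=float)
    rhos = t["mean_rho"].to_numpy(dtype=float)
    rho_min = rhos[np.argmin(sizes)]
    rho_max = rhos[np.argmax(sizes)]
    slope = float(stats.linregress(sizes, rhos).slope)
    converged = bool((rho_max - rho_min >= margin) and slope > 0)
    return ConvergenceSummary(float(rho_max), slope, converged)
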