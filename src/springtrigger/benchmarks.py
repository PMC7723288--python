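"""Canonical benchmark systems for validating the EDM machinery.

These generate the standard test-bed series of the empirical-dynamic-
modeling literature — the chaotic logistic map (for the S-map nonlinearity
test) and a unidirectionally coupled logistic pair (for convergent cross
mapping) — plus a helper that wraps a regularly sampled series pair into
the package's embedding containers on a synthetic daily calendar.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import DailySeries, SampleSeries
from .edm import Embedding, build_embedding

__all__ = [
    "logistic_map",
    "ar1_series",
    "coupled_logistic_pair",
    "daily_embedding",
]


def logistic_map(
    n: int,
    r: float = 3.8,
    noise_cv: float = 0.0,
    seed: int = 0,
    burn: int = 100,
) -> np.ndarray:
    """Chaotic logistic map x(t+1) = r x (1 − x) with optional observation noise."""
    rng = np.random.default_rng(seed)
    total = n + burn
    x = np.empty(total)
    x[0] = rng.uniform(0.2, 0.8)
    for t in range(1, total):
        x[t] = r * x[t - 1] * (1.0 - x[t - 1])
    obs = x[burn:]
    if noise_cv > 0:
        obs = obs * (1.0 + rng.normal(0.0, noise_cv, size=n))
    return obs


def ar1_series(n: int, coeff: float = 0.7, sd: float = 1.0, seed: int = 0) -> np.ndarray:
    """Stationary linear AR(1) series, shifted to be positive (count-like)."""
    rng = np.random.default_rng(seed)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd / np.sqrt(1.0 - coeff * coeff))
    for t in range(1, n):
        x[t] = coeff * x[t - 1] + rng.normal(0.0, sd)
    return x - x.min() + 0.1


def coupled_logistic_pair(
    n: int,
    beta: float = 0.32,
    r_driver: float = 3.7,
    r_response: float = 3.8,
    seed: int = 0,
    burn: int = 100,
):
    """Unidirectionally coupled logistic maps: chaotic driver y forcing response x.

    ``beta = 0`` gives two independent maps (the surrogate/null pair).
    Returns ``(response, driver)`` after discarding the transient.
    """
    rng = np.random.default_rng(seed)
    total = n + burn
    x = np.empty(total)
    y = np.empty(total)
    x[0], y[0] = rng.uniform(0.2, 0.8, size=2)
    for t in range(1, total):
        y[t] = y[t - 1] * (r_driver - r_driver * y[t - 1])
        x[t] = np.clip(
            x[t - 1] * (r_response - r_response * x[t - 1] - beta * y[t - 1]), 0.0, 1.0
        )
    return x[burn:], y[burn:]


def daily_embedding(
    series: np.ndarray,
    covariate: np.ndarray | None = None,
    lags=(1, 2),
    scale: float = 1000.0,
) -> Embedding:
    """Embed a regularly sampled series on a synthetic daily calendar.

    The series is scaled to count-like magnitude; the covariate (driver)
    defaults to zeros when only forecast skill of the series itself is of
    interest.
    """
    n = len(series)
    dates = pd.date_range("2015-01-01", periods=n, freq="D")
    eggs = SampleSeries.from_pairs(dates, np.maximum(np.asarray(series, float), 0.0) * scale)
    cov = np.zeros(n) if covariate is None else np.asarray(covariate, float)
    daily = DailySeries.from_pairs(dates, cov)
    return build_embedding(eggs, daily, lags=lags, tolerance=0)
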