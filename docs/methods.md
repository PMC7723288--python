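# Methods

This note documents the models, estimators, and numerical choices behind
`springtrigger`, and what the synthetic studies used by the test suite do and
do not establish about real monitoring data.

## Data model

Two containers carry the analysis. A `DailySeries` holds at most one value
per calendar date; missing days are simply absent and are never filled or
interpolated — every downstream operation must cope with gaps explicitly. A
`SampleSeries` holds irregularly dated nonnegative tow counts, optionally
with per-species integer columns whose row sums may not exceed the total
(unidentified eggs are allowed). Raw sub-hourly SST logs are reduced to daily
means by arithmetic averaging over the local calendar date of each reading;
timestamps carry no timezone arithmetic. CSV floats are parsed with exact
(shortest-repr) semantics so that write→read round-trips are bit-identical.

The centered moving average of width *w* (odd) at date *t* averages the
available values in [t−(w−1)/2, t+(w−1)/2] provided at least half of the
window days carry a value, and emits nothing otherwise; output dates are
restricted to the observed span. This 50% rule avoids silently biased means
near long gaps while still tolerating the routine 1–2 day holes of pier
records.

## The spring temperature trigger

For year *y* and window length *L* days, windows whose **last** day
traverses the spring interval (April 1 – June 18 by default, both traversal
endpoints inclusive) are examined in daily steps. Within one window the rise
is the maximum of T[j] − T[i] over ordered pairs i &lt; j of available days
(an endpoint-difference variant, `rise="endpoints"`, is available as a
configuration alternative); if every pair declines the rise is 0. The STT is
the maximum rise over window positions. Ties break deterministically:
earliest rise start, then shortest span within a window; earliest window end
across windows. Window positions with fewer than 80% of their days present
are skipped; a year in which every position is skipped raises an error
rather than returning a degraded value. The implementation is an O(n)
running-minimum per window and is verified exactly, year by year, against
brute-force enumeration of all eligible day pairs.

Two invariances pin the statistic down: adding a constant to all
temperatures leaves the STT unchanged, and scaling temperatures scales it
linearly. The STT is non-decreasing in *L*, since a longer window admits
every shorter window's pairs — the elementary fact behind the scan-maximum
hazard below.

Leap years resolve (month, day) boundaries per year; February 29 belongs to
winter. Peak summer eggs is the maximum single-tow count within the summer
interval (June 1 – August 31), ties to the earliest date. The trigger model
is ordinary least squares of peak on STT with Pearson ρ (scipy), refusing
zero-variance inputs and fewer than three years. Predictions are reported
as-is, even when negative, with a logged warning. Shannon diversity of a
peak sample is −Σ p ln p over positive species counts (nats).

## Structural-sensitivity audits

Each audit re-runs the trigger→peak correlation while varying one structural
choice; every scan's baseline cell reproduces the corresponding single-call
analysis exactly (this is asserted in tests, not assumed).

* **Window-width scan**: ρ(L) for L on a grid (default 7–56 d, weekly
  steps).
* **Boundary surface**: ρ over day shifts of the spring end and summer start
  (default ±21 d, daily steps). Internally, per-window-end rises are
  computed once per year and the per-offset STT is a running maximum over
  window ends — cell-for-cell identical to calling the trigger directly,
  verified in tests. Cells whose shifted interval is empty, or with fewer
  than three usable years, are marked invalid, never dropped.
* **Any-time trigger**: the window end may range from January 28 to the day
  before the *annual* (January–December) egg peak; years whose peak falls on
  or before January 28 are excluded with a warning.
* **Smoothing scan**: the STT recomputed on moving-averaged SST (widths
  1–31 d, odd); width 1 equals the unsmoothed analysis exactly.
* **Lagged cross-correlation**: each winter-day SST is paired with the
  collection nearest t + delay within ±2 d (ties to the earlier tow),
  delays 0–180 d; delays with fewer than 3 pairs are invalid.
* **Seasonal aggregate**: mean December–February SST (winter of year *y*
  ends in *y*) against mean March–August egg abundance.
* **Annual-variable matrix**: pairwise Pearson ρ among STT, peak summer
  eggs, mean summer eggs, and mean winter SST.

The audits' scientific content is the *superset property*: a maximum over a
grid of configurations is monotonically non-decreasing as the grid grows, so
on data where no true coupling exists the scan maximum systematically
exceeds the correlation of any single pre-registered configuration. The
package quantifies that inflation by Monte-Carlo on null synthetic studies
rather than by analytic multiple-testing correction, mirroring how the
hazard arises in practice (no correction is applied when a "robust-looking"
configuration is selected by eye).

## Empirical dynamic modeling on irregular samples

The embedding has one row per collection date *t* that has (a) a covariate
value at *t* and (b) collections within ±1 d of the nominal lags 7 and 14 d
(configurable); when several tows fall in a tolerance window the one nearest
the nominal lag is used, ties to the earlier. This filtering discards data
but manufactures none.

**S-map.** The forecast target is the row's own-time egg value; the
predictors are the *strictly lagged* coordinates (plus an intercept), and
S-map distances are taken in that predictor space. (Including the own-time
value among predictors would make the regression an identity map and void
the θ-scan; the nowcast form keeps the embedding's construction while
leaving a genuine forecasting problem.) For each target, rows within the
exclusion radius (default: the target only; a Theiler-style radius is
configurable) are left out, remaining rows are weighted by
w<sub>i</sub> = exp(−θ d<sub>i</sub>/d̄) with d̄ the mean distance to the
target, and the weighted least-squares problem is solved by a rank-revealing
decomposition (`lstsq`), which yields the least-norm solution when the
weighted system is singular. At θ = 0 the procedure reduces exactly to
leave-one-out global OLS; this closed-form limit is asserted to 1e−8. The
nonlinearity flag fires when max ρ(θ) − ρ(0) exceeds 0.02 (configurable).
The discrimination properties — gain &gt; 0.05 on the noisy chaotic logistic
map, ≤ 0.01 on linear AR(1) series — are asserted over 50 seeded replicates
each.

**CCM.** Cross mapping predicts the putative driver (temperature) from the
egg-state geometry: for each target row, a library of a given size is drawn
uniformly without replacement from the rows within the calendar-proximity
limit (default |Δdate| ≤ 90 d; a circular day-of-year mode is available —
the two readings differ materially, since day-of-year pools span all years
and absolute pools do not), the k = 4 nearest library rows in the full
lag-coordinate space predict the covariate by exponentially weighted
average u<sub>i</sub> = exp(−d<sub>i</sub>/d₁) (equal weights when d₁ = 0),
and the per-draw skill is the Pearson correlation of predictions with
observations over all usable targets. Targets whose pool is smaller than
the library size are skipped and counted. Convergence is declared when mean
skill at the largest library exceeds that at the smallest by ≥ 0.1 with a
positive trend slope. All draws flow from one `numpy` Generator seeded by
the caller; reruns are identical draw-for-draw.

The CCM validation benchmark is a unidirectionally coupled logistic pair:
driver y(t+1) = 3.7 y (1 − y) (chaotic; an autonomous map at 3.5 settles
onto a period-4 cycle after its transient, which would make the driver
trivially predictable and convergence an artifact of the transient),
response x(t+1) = x (3.8 − 3.8x − 0.32y) clipped to [0, 1], 100-step
burn-in. The proximity limit is set global for this benchmark because the
pair has no seasonality to control for; β = 0 gives the independent
surrogate pair, for which mean cross-map skill is centered on zero.

## The synthetic study generator

`generate_study` emulates the structure the analysis assumes, with one seed
governing every draw through separate named streams (events, SST noise, egg
noise), so SST and eggs agree on the ground truth without sharing state.

SST is an annual cosine (period 365 d, warmest day-of-year 225) of mean
17.5 °C and amplitude 4 °C, plus AR(1) anomalies with coefficient 0.9 and
innovation sd 0.17 °C (stationary sd ≈ 0.39 °C — persistent, marine-
heatwave-like residuals rather than day-to-day white noise), plus one
warming event per year: a triangular bump ramping up linearly over 10 d and
relaxing over 10 d (a permanent step would accumulate across years and
contaminate winter statistics; the symmetric bump keeps the windowed rise
equal to the injected magnitude). Event magnitudes are uniform on
0.75–5.25 °C; ramp starts are uniform on day-of-year 75–151, i.e. events
range over essentially the whole spring, including near the season
boundaries where structural shifts can include or exclude them.

The latent egg curve is a 10 eggs/tow baseline plus one Gaussian peak per
year (sd 12 d) centered uniformly in day-of-year 152–240 — peak timing
ranges over the whole summer, as observed peak timing does. The peak height
is 200 + 150 × (event magnitude) + N(0, 30) eggs/tow in coupled mode; under
the null the height is drawn from the same marginal but independently of
the events. Tows occur at uniform 2–5 d gaps; each tow observes the latent
curve times a mean-one lognormal patchiness factor (CV 0.10 — real tow
series are far spikier, but heavier patchiness would bias the annual
maximum upward and mask the coupling being tested) and is rounded to a
nonnegative integer (a Poisson observation model is a flag).

Several of these defaults were calibrated jointly rather than chosen
independently, because the validation regimes constrain each other: slope
and ρ recovery require the event-magnitude spread to dominate the nuisance
variability of the windowed maximum; the smoothing-degradation regime
requires SST noise persistent enough to survive 31-day averaging; and the
null-fragility regime requires event and peak timing spread wide enough,
and tow-level noise present, for boundary shifts to genuinely re-select
events and re-draw peaks. The calibrated generator reproduces all three
regimes at once; the numbers are asserted in `tests/test_acceptance.py` and
recomputed by `scripts/acceptance.py`.

What the synthetic studies do **not** establish: real egg series have
multi-species composition, secondary (e.g. spring) peaks, red-tide-scale
disturbances, and heavier-tailed patchiness; real SST has QC gaps,
non-sinusoidal seasonality, and interannual trends. Passing the recovery
tests shows the estimators are correct and the audits behave as designed,
not that a real trigger→peak correlation of similar strength would be
trustworthy — the null-fragility result argues precisely for caution there.

## Numerical and interface choices

* Pearson correlations inside scans use a direct centered-dot-product
  formula (clipped to [−1, 1]); model fits use `scipy.stats.linregress`.
* Grid cells and scan years that fail (insufficient coverage, empty
  intervals, n &lt; 3, zero variance) are marked invalid or excluded with a
  logged warning — never silently interpolated.
* Problem sizes in the test suite (7-year studies, 50–100 replicates,
  n = 300–400 benchmark series, 20 CCM draws) are chosen so the full suite
  runs in a few minutes while keeping Monte-Carlo error well inside the
  asserted margins.
* CLI outputs contain no timestamps; a run is a pure function of config +
  seed, and the resolved config and its hash are written next to every
  output. Floats round-trip through CSV at full precision.
* Output conventions: `TriggerResult` records the achieving window and rise
  endpoints so a reported STT can be traced to specific dates; all scans
  emit tidy CSV (grid columns + rho + n + valid).

## Known limitations

* The any-time trigger and boundary scans assume egg years are calendar
  years; winter-spanning spawning seasons would need a season-anchored year
  definition.
* The S-map embedding reuses the CCM embedding (dimension 3, lags 7/14 d)
  by default; no automated embedding-dimension search is provided.
* CCM significance is assessed by convergence and by surrogate comparison
  in the tests; no surrogate-data test is built into the library itself.
* With absolute-date proximity and sparse sampling, large library sizes can
  have empty eligible-target sets (reported as invalid rows with
  `n_targets = 0`); the day-of-year mode pools across years and does not
  have this limit.
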