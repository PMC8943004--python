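# Methods

This note documents the models, numerical choices and limitations of the
package. Everything quantitative stated here is computed by the test suite
or by `scripts/acceptance.py`; nothing is quoted from elsewhere.

## The analysis problem

A nocturnal insectivorous migrant alternates stopovers with nightly flight
bouts. The scientific question is whether its nightly tactics — whether it
migrates at dusk/night/dawn, how fast it travels per day, how high it flies
— differ between ecological barriers (deserts, Mediterranean scrub,
tropical moist forest) and hospitable semi-open biomes. Two device classes
feed the analysis: multi-sensor archival loggers (activity, pressure,
light, temperature every 5 min) and archival GPS loggers (one fix per day
at 00:00 GMT). Position for the multi-sensor birds must be inferred from
light alone, with errors of hundreds of km, so biome assignment must
respect positional uncertainty.

## Synthetic study system

The generator (`nocmig.synthetic`) defines the study conditions under which
the pipeline is validated:

* **Route and calendar.** Great-circle waypoints from a north-temperate
  breeding site (5.5°E, 51.1°N) to a southern-African wintering site
  (25°E, 18°S), departing 5 August, 65 days at 5-min resolution, one
  4-day stopover in week two. ~40 days are migration; once the final
  waypoint is reached the bird is sedentary, providing the stationary
  wintering window that zenith calibration requires. The departure month
  and a wintering site well away from the equator are biological features
  of the system, and they matter methodologically: near-equinox migration
  and near-equatorial wintering are the known degenerate regimes of
  day-length latitude estimation.
* **Behaviour.** Each dusk/night/dawn window of a non-stopover day is flown
  as a whole with a Bernoulli probability that depends on the biome
  category under the bird: dusk 0.75 (barrier) vs 0.40 (hospitable), night
  0.85 vs 0.80, dawn 0.35 vs 0.30. Migrating runs are extended to ≥ 60 min
  so the bout definition is recoverable. Movement happens only while
  migrating, at 50 km/h along the route. These probabilities encode the
  qualitative effect structure under study (a strong dusk barrier effect,
  no night/dawn effect) at plausible magnitudes (the dusk log-odds gap is
  ≈ 1.5); they are conditions, not tuning knobs.
* **Sensors.** Activity per state is Gaussian with means 1/15/60 logger
  units (sd 0.5/2/5) — well separated, as flapping flight is against rest
  in real accelerometry. Pressure is the ISA inverse of true altitude plus
  1 hPa noise (≈ 8 m). Flight altitude is 1600 m (barrier) vs 800 m
  (hospitable) above ground (200 m). GPS altitude noise is 10 m.
* **Light.** Relative irradiance is `c + (1-c) sin(e)` above the horizon
  and `c · exp(e / k)` below it (elevation `e`, horizon fraction
  `c = 0.05`, e-folding `k = 3°`), scaled to 1000 units with a floor of
  1.0. The exponential twilight tail makes log-light linear in solar
  elevation below the horizon, which is what lets a light threshold
  correspond to a zenith angle deeper than 90° — a clipped-sine model with
  no tail cannot produce twilight-zenith calibration at all. Shading is one
  multiplicative lognormal factor per half solar day (σ = 0.3): shading
  varies on cloud/vegetation timescales, and i.i.d. per-sample noise would
  generate spurious threshold crossings inside a single twilight rather
  than the delay/advance structure real shading produces.
* **Rasters.** Biome, elevation and land-sea grids share one geotransform;
  biomes are latitude bands (barrier band 8–32°N as the desert belt),
  written as ESRI ASCII grids.

What the generator deliberately omits: wind and thermals, sensor drift,
magnetometer data, within-biome habitat heterogeneity, and longitude-
dependent biome structure. Passing tests therefore demonstrate that the
*inference chain* is correct and well calibrated under the stated noise
model — not that real nightjar data would yield these effect sizes.

## Activity classification and bouts

1-D k-means with centroids initialised at the 1/(2k), 3/(2k), … quantiles
and Lloyd iterations to a 1e-10 tolerance (max 500). Quantile
initialisation makes the classifier deterministic and, in 1-D with ordered
clusters, near-optimal — the test suite checks it against an exact
dynamic-programming 1-D k-means oracle. Classification is per individual
(each tag has its own activity scale). "Uninterrupted" high activity is
strict: any non-high interval or recording gap breaks a run
(`gap_tolerance` defaults to 0, configurable). A night is attributed to the
date of its sunset; stopovers are maximal runs of bout-free nights.

## Solar geometry

NOAA-calculator (truncated Meeus) solar position; sunrise/sunset at zenith
90.833° (0.567° refraction + 0.267° solar radius), astronomical twilight at
108°. The independent test oracle is the Astronomical Almanac low-precision
algorithm, agreeing within 0.2°. Dusk vs dawn inside the twilight band is
decided by the sign of the elevation change over ±5 min, which keeps the
four labels an exact partition of the day; where astronomical twilight
never ends (polar summer), the band splits at local solar midnight by the
same sign rule.

## Geolocation

**Twilight detection.** Linear interpolation of the threshold crossing
between 5-min samples. Short opposite-type episodes (a dark dip or light
blip shorter than 4 h) are removed pairwise, then any same-type crossing
within 4 h of the last kept one is suppressed. The cost is that genuine
nights shorter than 4 h (polar summer) would be dropped; that regime is
outside the species' migration window.

**Threshold positions.** Longitude from the pair midpoint versus solar
noon/midnight. Latitude solves
`sin(lat)sin(δ) + cos(lat)cos(δ)cos(H) = cos(z)` by sign-change scan plus
bisection to 0.01°; with multiple roots the one nearest a caller-supplied
hint is taken. Near the equinoxes (|δ| < 1.5°) unsolvable day lengths are
flagged indeterminate rather than guessed.

**Calibration.** Two zenith angles are estimated on the stationary window,
because they answer different questions:

1. the **effective zenith** (grid 90.5–108°, step 0.25°) minimises the
   variance of the latitude series; it absorbs the median shading delay and
   is the right angle for threshold *positioning*;
2. the **zero-delay zenith** anchors the delay *distribution* for the MCMC
   likelihood. A zenith change shifts every delay by nearly a constant, so
   the L-scale and L-skewness of the residuals are shift-invariant: the
   L-skewness pins the lognormal shape (Hosking's approximation), the
   L-scale then implies the mean of the positive delay part, and the
   zero-delay zenith is the angle whose residual mean matches. This
   moment-matching is consistent when delays are lognormal and degrades to
   "mean delay = 0" as the spread vanishes. Simpler rules fail: aligning a
   fixed low quantile to zero is biased by the family's nonzero lower
   quantile, and profile-likelihood/KS criteria are degenerate in the shift
   direction.

Separating the two angles matters because a minute of shading delay maps to
a latitude-dependent zenith shift (the sun crosses the twilight band at
different rates at different latitudes); reusing the effective zenith in
the likelihood biases positions away from the calibration latitude.

**MCMC refinement.** One location parameter per twilight event (two per
day). A nocturnal migrant is stationary through the day, so each sunrise
shares its parameter with the same day's sunset (`day_roost_groups`);
stopover and wintering events are likewise grouped into single locations.
The log-target sums, per parameter: the lognormal twilight-delay
log-density (observed-minus-predicted for dawn, reversed for dusk, with a
smooth quadratic continuation below 0.05 min so the target stays finite),
the gamma speed prior on great-circle speed between consecutive parameters
(floored at 10⁻³ km/h), and a land-mask indicator for stationary (grouped)
parameters. The first parameter is anchored at the deployment site.
Declination and the equation of time are precomputed at each observed event
time (drift < 0.5°/day, far below twilight noise), making each prediction a
handful of vectorised operations. Updates are an even/odd checkerboard of
Gaussian random-walk proposals (latitude proposal 2× the longitude scale —
latitude is the weakly determined axis), a valid block Gibbs scheme that
vectorises each half-sweep. Schedule: 250 burn-in sweeps, 3 tuning runs of
300 sweeps with per-parameter scale adaptation toward 23% acceptance, 2000
retained sweeps; all configurable. CI boxes are per-axis equal-tailed
quantiles (97.5% → 1.25%/98.75%).

Validation on 20 replicate tracks with calibrated lognormal twilight noise
(scale 3.5 min, σ = 0.6): pooled 97.5% CI coverage ≈ 91% and median
great-circle error reduced from ≈ 140 km (threshold) to ≈ 105 km (refined)
over the migration period. Coverage is measured on migration-period
estimates — the wintering period serves calibration, and its grouped
location would otherwise dominate the count.

## Altitude and GPS metrics

ISA troposphere only — no correction from the tag's temperature sensor,
since the target quantity is relative daily altitude change. The daily
window is noon-to-noon UTC so a night's flight lands on one day, matching
the night attribution used for activity. Travel-segment retention replaces
visual inspection with a reproducible rule: a day below 25 km/day is an
interruption (configurable); the operation is idempotent. Distances use the
haversine on a 6371.0088 km sphere; the sphere-vs-ellipsoid error is far
below positional noise. DEM sampling is nearest-cell, consistent with the
categorical biome sampling.

## Biomes under positional uncertainty

Point sampling uses the half-open cell convention [west, east) × [south,
north) so edge hits are deterministic. Zonal majority counts cells whose
centres fall in the CI box, weighted by cos(latitude) (cell-count weighting
available); ties break to the lower code with a flag. Biomes observed fewer
than twice within a grouping are excluded — a singleton biome cannot
support a contrast. The barrier/hospitable map ships as an editable
dictionary with deserts, Mediterranean scrub and tropical moist broadleaf
forest as the default barriers.

## Mixed models

The binomial random-intercept GLMM is fitted by maximum likelihood with a
Laplace approximation of the marginal likelihood (adaptive Gauss–Hermite
optional): inner Newton iterations find each group's conditional mode
(vectorised across groups, warm-started between objective evaluations);
the outer optimisation is L-BFGS-B over (β, log σ) with log σ bounded in
[log 1e-4, log 50]. Standard errors come from the finite-difference Hessian
at the optimum. Convergence: step tolerance 1e-11, gradient 1e-7, inner
mode tolerance 1e-10. The fit is cross-checked in the test suite against an
independent reference implementation (R glmmTMB) to ≈ 0.02 on coefficients
and standard errors, and reduces to plain logistic regression when the
variance is pinned to zero. Separation (an outcome constant within a
category × period cell) raises a diagnostic error naming the cell.

Gaussian outcomes use statsmodels MixedLM with `reml=False` (ML, matching
the binomial fits for likelihood-ratio testing); if L-BFGS collapses to a
degenerate profile, BFGS and Powell are tried in turn and the best finite
converged fit kept. A single-individual frame falls back to OLS with a
warning. The zero-inflated model is a two-part factorisation — an
intercept-only Bernoulli on 1{y = 0} and a Gaussian mixed model on the
positive part — whose joint likelihood is exact ML because the parts share
no parameters.

Reference levels are hospitable and dusk, so "positive estimate = barrier
effect". Contrasts are barrier − hospitable on the link scale per period,
with multiplicity adjustment by integrating the joint multivariate-*t* of
the t-ratios (correlation from the fixed-effect covariance, residual df =
n_obs − rank; the QMC integration is seeded for reproducibility; Šidák is
the fallback). Residual df rather than Satterthwaite keeps the contract
simple and matches the reported-output convention of the motivating
analysis. The previous-step covariate is the lagged outcome within
individual (configurable via `lag_column`); the first interval per
individual is dropped, as are stopover days and day-period rows.

## Pipeline

Stages run in dependency order: simulate → classify → geolocate → altitude
→ metrics → biomes → fit. All randomness flows from one root seed through
named substreams (per individual, per module), so a re-run with the same
config is byte-identical. Every CSV artifact carries `#` header comments
with package version, config hash (output path excluded) and seed; a stage
failure writes a `FAILED` marker and exits nonzero, keeping partial
outputs. The interval-level model frame classifies each 5-min record's
period at the estimated daily position and attaches the day's majority
biome; at the default scale (3 individuals, 65 days) a full run takes
roughly 15 s on one CPU.

## Problem sizes

Defaults were chosen as the smallest sizes at which each property is
comfortably identified: 65-day tracks (≈ 18 700 records/individual), 3
individuals in the pipeline, 20 replicate tracks for MCMC validation, 50
(power) and 100 (null) replicates at 20 individuals × 2000 intervals for
the contrast operating characteristics, 10⁴ points for classifier accuracy.

## Known limitations

* The twilight-error model is stationary in time and space; real shading
  varies with habitat, so the calibrated spread can understate
  migration-period error. The light-trace simulation (as opposed to the
  direct lognormal-delay observation model) produces exactly this
  mismatch, and coverage under it is below nominal — a faithful
  reproduction of a real limitation of the method.
* Latitude is weakly identified within ±1.5° of declination zero; such
  twilight pairs are flagged and the movement prior carries them.
* The zero-inflation part is intercept-only; covariate-dependent inflation
  would need a joint fit.
* The Laplace approximation biases variance components slightly downward
  with few groups (visible as σ² underestimation in the recovery tests);
  fixed effects and contrasts are unaffected at the scales used here.
* `daily_travel_speed` normalises over irregular fix gaps and flags the
  record; it never pools distance across missing days.
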