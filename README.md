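# nocmig

Multi-sensor biologging analysis of nocturnal bird migration: how a small
crepuscular migrant (the European Nightjar, *Caprimulgus europaeus*, is the
motivating species) changes its nightly migration tactics when crossing
ecological barriers — deserts, Mediterranean scrub, tropical moist forest —
versus hospitable semi-open biomes.

The package is for movement ecologists working with two device classes:

* **multi-sensor archival loggers** recording activity (sum of absolute
  z-axis acceleration differences), air pressure, light and temperature at
  5-min resolution, from which behaviour and position must be *inferred*;
* **archival GPS loggers** recording one fix per day at 00:00 GMT.

Because raw tracking data of this kind are rarely public, the package ships
a first-class synthetic-data generator that produces ground-truth tracks,
sensor streams, GPS fixes and biome/elevation/land-sea rasters with the
statistical structure the analysis assumes, so every stage is testable
end to end against known truth.

## What it computes

**Activity and flight bouts.** 1-D k-means (deterministic quantile
initialisation) classifies the activity index into inactive < low < high;
migratory flight bouts are maximal runs of uninterrupted high activity of at
least 60 min; stopovers are runs of nights with no bout. Intervals are then
reduced to two binaries: *migrating* (inside a bout) and *foraging* (low or
high activity outside a bout).

**Light-level geolocation.** Twilight events are threshold crossings of the
light trace. The threshold method gives initial positions: longitude from
the twilight-pair midpoint versus solar noon/midnight; latitude from day
length given solar declination and a sun zenith angle `z`. Hill–Ekstrom
calibration on the stationary wintering period selects `z` by minimising
the variance of the latitude series and fits a one-sided lognormal to the
twilight-timing error caused by sensor shading. An Estelle-type
Metropolis-within-Gibbs sampler then refines one location per twilight
event under

* the twilight-time likelihood (lognormal delay model),
* a gamma flight-speed prior between consecutive locations
  (shape 2.2, rate 0.08 km/h; mean 27.5 km/h),
* a land mask forbidding stationary positions over water,

with the first position anchored at the deployment site and stopover
locations shared. Per-position 97.5% credible-interval boxes come from the
1.25%/98.75% posterior quantiles per axis.

**Altitude.** Pressure converts to altitude above sea level with the ISA
troposphere relation `H = -(T0/L) (1 - (P/P0)^(1/5.2561))`,
P0 = 1013.25 hPa, T0 = 288.15 K, L = -0.0065 deg/m; the daily altitude
change is the noon-to-noon max - min.

**GPS metrics.** Daily travel speed (great-circle km/day between
consecutive fixes), travel-segment retention (interruption days below
25 km/day removed), and altitude above ground (fix altitude minus terrain,
clamped at 0).

**Biomes.** GPS fixes are point-sampled on the categorical biome raster;
geolocation estimates take the *majority* biome within their 97.5% CI box
(cosine-latitude area weighting). Biomes map to ecological **barrier**
(Desert and Xeric Shrubland, Mediterranean Forest/Woodland/Scrub, Tropical
Moist Broadleaf Forest) versus **hospitable** (semi-open) categories.

**Inference.** Binomial GLMMs (logit link, Laplace-approximate ML, random
intercept per individual) model migration and foraging probability as
`outcome ~ category * period + prev_state + (1 | individual)` over dusk,
night and dawn; Gaussian mixed models handle daily altitude change and
travel speed, and a zero-inflated Gaussian mixed model handles flight
altitude above ground. Barrier-minus-hospitable contrasts per period are
multiplicity-adjusted by multivariate-*t* integration at residual degrees
of freedom; likelihood-ratio tests compare nested fits.

## Worked example

```python
from nocmig import synthetic as syn, activity

cfg = syn.SimulationConfig(seed=7, stopover_schedule=((12, 4),))
track = syn.simulate_track(cfg)             # 65-day ground-truth migration
sensors = syn.simulate_sensor_series(track) # 5-min logger records

labels = activity.classify_activity(sensors)
bouts = activity.detect_flight_bouts(labels)
labels = activity.derive_binary_variables(labels, bouts)
print(f"{len(track.data)} five-minute records, {len(bouts)} flight bouts")
```

prints

```
18720 five-minute records, 20 flight bouts
```

and the detected bouts recover the generated migratory flights exactly
(recall and precision 100% on this track, longest bout 680 min).

The whole analysis runs from the command line:

```bash
nocmig run-all --out run1 --seed 1
```

which simulates three individuals, runs every stage and writes all
intermediates plus `model_summaries.txt`. With seed 1 the migration-
probability model is

```
period    Estimate       SE      df  t.ratio  p.value
dusk         1.774    0.424    7431    4.180    0.000
night       -0.224    0.326    7431   -0.685    0.870
dawn        -0.341    0.374    7431   -0.910    0.741
```

i.e. the probability of migrating at dusk is significantly higher inside
ecological barriers (log-odds contrast +1.77), while night and dawn show no
category difference — the "rush through barriers" tactic the generator
encodes, recovered through the full inference chain (classification,
geolocation with ~100-150 km median position error, zonal biome assignment,
mixed models). The speed, altitude-change and flight-altitude models
likewise return positive barrier effects.

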