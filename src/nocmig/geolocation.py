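"""Light-level geolocation: twilight detection, threshold positions,
Hill-Ekstrom calibration and MCMC track refinement.

The raw observable is the time the logged light level crosses a fixed
threshold at dawn and dusk.  The threshold method converts a twilight pair
into a position: longitude from the pair midpoint versus solar noon/midnight,
latitude from day length given the solar declination and a sun zenith angle.
The zenith angle and the twilight-timing error caused by shading of the
sensor are calibrated on a known-stationary (wintering) period by minimising
the variance of the latitude series (Hill-Ekstrom calibration).  Finally a
Metropolis-within-Gibbs sampler refines the whole position sequence under a
twilight-time likelihood, a gamma flight-speed prior between consecutive
positions, and a land mask forbidding stationary positions over water,
yielding posterior samples and 97.5% credible-interval boxes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import erf as special_erf

from . import solar
from .gpsmetrics import EARTH_RADIUS_KM, great_circle_km
from .rasters import Raster

__all__ = [
    "CalibrationModel",
    "EstellePriors",
    "McmcSchedule",
    "detect_twilights",
    "threshold_positions",
    "hill_ekstrom_calibrate",
    "refine_positions_mcmc",
    "credible_interval",
    "daily_positions",
]


# ---------------------------------------------------------------------------
# twilight detection


def detect_twilights(
    series,
    light_threshold: float,
    min_same_type_gap_h: float = 4.0,
) -> pd.DataFrame:
    """Threshold crossings of the light trace: sunrises (up) and sunsets (down).

    Crossing times are linearly interpolated between the bracketing samples.
    A crossing of the same type within ``min_same_type_gap_h`` of the last
    kept one is suppressed (guards against brief cloud dips).  Returns a
    frame (date, type, time, excluded); emits a warning if any 48-h stretch
    contains no crossing.
    """
    data = series.data if hasattr(series, "data") else series
    light = data["light"].to_numpy(dtype=float)
    t = pd.to_datetime(data["timestamp"]).to_numpy()

    up = np.where((light[:-1] < light_threshold) & (light[1:] >= light_threshold))[0]
    down = np.where((light[:-1] >= light_threshold) & (light[1:] < light_threshold))[0]

    events = []
    for idxs, etype in ((up, "sunrise"), (down, "sunset")):
        for i in idxs:
            frac = (light_threshold - light[i]) / (light[i + 1] - light[i])
            when = t[i] + frac * (t[i + 1] - t[i])
            events.append({"type": etype, "time": pd.Timestamp(when)})
    events.sort(key=lambda e: e["time"])

    # drop short dark dips (sunset then sunrise) and light blips (sunrise
    # then sunset) lasting less than the guard interval, then suppress any
    # same-type crossing within the guard of the last kept one
    gap = pd.Timedelta(hours=min_same_type_gap_h)
    changed = True
    while changed and len(events) >= 2:
        changed = False
        for i in range(len(events) - 1):
            a, b = events[i], events[i + 1]
            if a["type"] != b["type"] and b["time"] - a["time"] < gap:
                del events[i : i + 2]
                changed = True
                break

    kept, last_kept = [], {}
    for e in events:
        prev = last_kept.get(e["type"])
        if prev is not None and e["time"] - prev < gap:
            continue
        last_kept[e["type"]] = e["time"]
        kept.append(e)

    if len(t) and (not kept or np.ptp(t) > np.timedelta64(2, "D")):
        times = [np.datetime64(e["time"]) for e in kept]
        bounds = [np.datetime64(t[0])] + times + [np.datetime64(t[-1])]
        gaps = np.diff(np.array(bounds, dtype="datetime64[s]"))
        if not kept or (gaps > np.timedelta64(48, "h")).any():
            warnings.warn("no twilight crossing within a 48-h window; day(s) skipped")

    out = pd.DataFrame(
        {
            "date": [e["time"].date() for e in kept],
            "type": [e["type"] for e in kept],
            "time": [e["time"] for e in kept],
            "excluded": False,
        }
    )
    return out


# ---------------------------------------------------------------------------
# threshold positions


def _minutes_of_day(ts: np.ndarray) -> np.ndarray:
    s = ts.astype("datetime64[s]")
    return (s - s.astype("datetime64[D]").astype("datetime64[s]")) / np.timedelta64(60, "s")


def _wrap_lon(lon):
    return (np.asarray(lon) + 180.0) % 360.0 - 180.0


def _latitude_from_daylength(day_len_min, decl_deg, zenith_deg, hint, tol=0.01):
    """Solve sin(lat)sin(d) + cos(lat)cos(d)cos(H) = cos(z) for latitude.

    H is the half-day hour angle implied by the day length.  Solutions are
    found by scanning for sign changes and bisecting; of multiple roots the
    one nearest ``hint`` is returned.  Returns (lat, residual_ok).
    """
    H = np.deg2rad(day_len_min / 8.0)  # 4 min per degree, half the day
    d = np.deg2rad(decl_deg)
    cz = np.cos(np.deg2rad(zenith_deg))

    def f(phi_deg):
        p = np.deg2rad(phi_deg)
        return np.sin(p) * np.sin(d) + np.cos(p) * np.cos(d) * np.cos(H) - cz

    grid = np.linspace(-89.9, 89.9, 360)
    vals = f(grid)
    roots = []
    sign_change = np.where(np.signbit(vals[:-1]) != np.signbit(vals[1:]))[0]
    for i in sign_change:
        lo, hi = grid[i], grid[i + 1]
        flo = vals[i]
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            fm = f(mid)
            if np.signbit(fm) == np.signbit(flo):
                lo, flo = mid, fm
            else:
                hi = mid
            if hi - lo < tol / 4:
                break
        roots.append(0.5 * (lo + hi))
    if not roots:
        # no exact solution: return the latitude minimising |f|, flagged
        best = grid[np.argmin(np.abs(vals))]
        return float(best), False
    hint = 0.0 if hint is None else hint
    lat = min(roots, key=lambda r: abs(r - hint))
    return float(lat), True


def threshold_positions(
    twilights: pd.DataFrame,
    zenith_deg: float,
    lat_hint: float | None = None,
    equinox_decl_deg: float = 1.5,
) -> pd.DataFrame:
    """Initial position per consecutive twilight pair (two per day).

    Longitude comes from the pair midpoint versus solar noon (sunrise->sunset
    pair) or solar midnight (sunset->sunrise); latitude from the implied
    day length at the given zenith.  Near the equinoxes latitude may be
    indeterminate: rows with |declination| < ``equinox_decl_deg`` whose
    day-length equation has no solution are flagged (lat = NaN).
    """
    tw = twilights[~twilights["excluded"]].reset_index(drop=True)
    types = tw["type"].to_numpy()
    for i in range(1, len(types)):
        if types[i] == types[i - 1]:
            raise ValueError(f"non-alternating twilight events at row {i}")
    times = pd.to_datetime(tw["time"]).to_numpy().astype("datetime64[s]")

    rows = []
    for i in range(len(tw) - 1):
        t0, t1 = times[i], times[i + 1]
        first = types[i]
        mid = t0 + (t1 - t0) / 2
        decl, eqtime = solar.solar_declination_eqtime(mid)
        decl, eqtime = float(decl), float(eqtime)
        m_mid = float(_minutes_of_day(np.asarray(mid)))
        lon = (720.0 - eqtime - m_mid) / 4.0
        span_min = (t1 - t0) / np.timedelta64(60, "s")
        if first == "sunrise":  # day pair, midpoint is solar noon
            day_len = span_min
        else:  # night pair, midpoint is solar midnight
            lon += 180.0
            day_len = 1440.0 - span_min
        lon = float(_wrap_lon(lon))
        lat, solved = _latitude_from_daylength(day_len, decl, zenith_deg, lat_hint)
        indet = (not solved) and abs(decl) < equinox_decl_deg
        rows.append(
            {
                "index": i,
                "date": pd.Timestamp(t0).date(),
                "time_mid": pd.Timestamp(mid),
                "time_first": pd.Timestamp(t0),
                "time_second": pd.Timestamp(t1),
                "type_first": first,
                "lon": lon,
                "lat": np.nan if indet else lat,
                "lat_indeterminate": indet or not solved,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# calibration


@dataclass
class CalibrationModel:
    """Calibrated sun zenith angle and twilight-timing error distribution.

    The error distribution (minutes, one-sided: shading delays the dawn
    crossing and advances the dusk crossing) is given as a scipy-style
    family with parameters; ``mean_min`` is its mean.
    """

    zenith_deg: float  # zero-delay zenith used by the twilight likelihood
    family: str = "lognormal"  # or "gamma"
    shape: float = 0.5
    scale_min: float = 2.0  # exp(mu) for lognormal; scale for gamma
    offset_min: float = 0.0  # location shift of the delay distribution
    zenith_effective_deg: float | None = None  # variance-minimising zenith
    window: tuple | None = None
    residuals_min: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if not 90.0 < self.zenith_deg < 108.0:
            raise ValueError("calibrated zenith must lie in (90, 108) degrees")
        if self.shape <= 0 or self.scale_min <= 0:
            raise ValueError("error-distribution parameters must be positive")

    @property
    def mean_min(self) -> float:
        if self.family == "lognormal":
            core = float(self.scale_min * np.exp(self.shape**2 / 2.0))
        else:
            core = float(self.shape * self.scale_min)
        return core + self.offset_min

    def logpdf(self, r_min):
        """Log-density of a twilight delay of ``r_min`` minutes.

        Below a small floor the density is continued by a quadratic penalty
        so the MCMC target stays finite for slightly negative residuals.
        """
        r = np.asarray(r_min, dtype=float) - self.offset_min
        floor = 0.05
        rc = np.maximum(r, floor)
        if self.family == "lognormal":
            lp = stats.lognorm.logpdf(rc, s=self.shape, scale=self.scale_min)
        else:
            lp = stats.gamma.logpdf(rc, a=self.shape, scale=self.scale_min)
        penalty = np.where(r < floor, ((floor - r) / 1.0) ** 2, 0.0)
        return lp - penalty


def _predict_twilight_minutes(lon, lat, decl_deg, eqtime_min, zenith_deg, rising):
    """Closed-form threshold-crossing time (UTC minutes of day).

    Declination and equation of time are evaluated at the observed event
    time (they drift < 0.5 deg/day, well below twilight noise), which makes
    the prediction a handful of vectorised operations per event.
    """
    latr = np.deg2rad(lat)
    declr = np.deg2rad(decl_deg)
    cos_ha = (np.cos(np.deg2rad(zenith_deg)) - np.sin(latr) * np.sin(declr)) / (
        np.cos(latr) * np.cos(declr)
    )
    ha = np.rad2deg(np.arccos(np.clip(cos_ha, -1.0, 1.0)))
    absent = np.abs(cos_ha) > 1.0
    sign = np.where(rising, -1.0, 1.0)
    pred = 720.0 - 4.0 * lon - eqtime_min + sign * 4.0 * ha
    return pred, absent


def _twilight_residuals(twilights: pd.DataFrame, lon, lat, zenith_deg):
    """Observed-minus-predicted twilight delays (min), one per event.

    Sunrise residual = observed - predicted; sunset residual = predicted -
    observed, so shading makes both positive.  Events absent at the position
    yield NaN.
    """
    times = pd.to_datetime(twilights["time"]).to_numpy().astype("datetime64[s]")
    rising = (twilights["type"].to_numpy() == "sunrise")
    decl, eqtime = solar.solar_declination_eqtime(times)
    obs = _minutes_of_day(times)
    pred, absent = _predict_twilight_minutes(lon, lat, decl, eqtime, zenith_deg, rising)
    r = ((obs - pred + 720.0) % 1440.0) - 720.0
    r = np.where(rising, r, -r)
    return np.where(absent, np.nan, r)


def hill_ekstrom_calibrate(
    twilights: pd.DataFrame,
    min_days: int = 20,
    zenith_grid: np.ndarray | None = None,
    family: str = "lognormal",
    lat_hint: float | None = None,
    reference_zenith: float | None = None,
) -> CalibrationModel:
    """Calibrate zenith angle and twilight error on a stationary period.

    Two steps, both on the stationary window:

    1. grid-search the zenith (default 90.5-108 deg, step 0.25) minimising
       the variance of the latitude series from :func:`threshold_positions`
       — this *effective* zenith absorbs the median shading delay and is the
       right angle for threshold positioning (``zenith_effective_deg``);
    2. align the *zero-delay* zenith: at the median window position, find
       the zenith at which the lower 2.5% quantile of the twilight delays is
       zero, so the delays become one-sided, and fit the error family to
       them there.  This separation keeps the delay model valid at other
       latitudes, where a minute of shading maps to a different zenith shift.

    ``reference_zenith`` overrides step 2 with a known threshold zenith.
    """
    dates = pd.to_datetime(twilights.loc[~twilights["excluded"], "date"])
    if dates.nunique() < min_days:
        raise ValueError(f"calibration window shorter than {min_days} days of twilights")
    if zenith_grid is None:
        zenith_grid = np.arange(90.5, 108.0 + 1e-9, 0.25)

    best = (np.inf, None)
    for z in zenith_grid:
        pos = threshold_positions(twilights, z, lat_hint=lat_hint)
        lats = pos["lat"].to_numpy(dtype=float)
        lats = lats[np.isfinite(lats)]
        if lats.size < max(5, len(pos) // 2):
            continue
        v = float(np.var(lats))
        if v < best[0]:
            best = (v, float(z))
    if best[1] is None:
        raise ValueError("no zenith in the grid yields a solvable latitude series")
    zenith = best[1]

    pos = threshold_positions(twilights, zenith, lat_hint=lat_hint)
    lon0 = float(np.nanmedian(pos["lon"]))
    lat0 = float(np.nanmedian(pos["lat"]))

    lmom_sigma = None
    if reference_zenith is None:
        # Zero-delay zenith by moments of the shifted lognormal: changing the
        # zenith shifts every delay by (nearly) a constant, which leaves the
        # sample skewness and sd unchanged.  Skewness pins the lognormal
        # shape s via skew = (w + 2) sqrt(w - 1), w = exp(s^2); the family
        # then implies mean = sd / sqrt(w - 1), and the zenith is the angle
        # whose residual mean matches.  Consistent when delays are lognormal;
        # degrades gracefully to "mean delay = 0" as the spread vanishes.
        r0 = _twilight_residuals(twilights, lon0, lat0, zenith)
        r0 = r0[np.isfinite(r0)]
        sd0 = float(np.std(r0))
        lmom_sigma = None
        if sd0 < 0.2:
            target_mean = 0.0
        else:
            # Shifted-lognormal fit by L-moments (Hosking): the L-scale and
            # L-skewness are invariant to the zenith-induced shift; the
            # L-skewness pins the lognormal shape and the L-scale then
            # implies the mean of the positive delay part.
            x = np.sort(r0)
            n = len(x)
            j = np.arange(n)
            b0 = x.mean()
            b1 = (j / (n - 1) * x).mean()
            b2 = ((j * (j - 1)) / ((n - 1) * (n - 2)) * x).mean()
            l1, l2 = b0, 2 * b1 - b0
            t3 = np.clip((6 * b2 - 6 * b1 + b0) / max(l2, 1e-9), 0.02, 0.95)
            zq = np.sqrt(8.0 / 3.0) * stats.norm.ppf((1.0 + t3) / 2.0)
            lmom_sigma = float(np.clip(0.999281 * zq - 0.006118 * zq**3 + 0.000127 * zq**5,
                                       0.05, 2.5))
            target_mean = float(np.clip(l2 / special_erf(lmom_sigma / 2.0), 0.0, 8.0 * sd0))
        fine = np.arange(max(zenith - 5.0, 90.2), min(zenith + 5.0, 108.0), 0.05)
        best, z_for_resid = np.inf, zenith
        for z in fine:
            r = _twilight_residuals(twilights, lon0, lat0, z)
            r = r[np.isfinite(r)]
            if r.size < 10:
                continue
            gap = abs(float(np.mean(r)) - target_mean)
            if gap < best:
                best, z_for_resid = gap, float(z)
    else:
        z_for_resid = reference_zenith
    resid = _twilight_residuals(twilights, lon0, lat0, z_for_resid)
    resid = resid[np.isfinite(resid)]
    offset = 0.0
    rc = np.clip(resid, 0.05, None)
    if family == "lognormal":
        if reference_zenith is None and lmom_sigma is not None:
            # reuse the L-moment fit: MLE on clipped residuals is fragile
            # when solver noise pushes a few residuals to the clip floor
            shape = lmom_sigma
            scale = max(target_mean, 0.1) * np.exp(-(lmom_sigma**2) / 2.0)
        else:
            shape, _, scale = stats.lognorm.fit(rc, floc=0)
    elif family == "gamma":
        shape, _, scale = stats.gamma.fit(rc, floc=0)
    else:
        raise ValueError("family must be 'lognormal' or 'gamma'")
    window = (dates.min().date(), dates.max().date())
    return CalibrationModel(
        zenith_deg=z_for_resid,
        family=family,
        shape=float(shape),
        scale_min=float(scale),
        offset_min=offset,
        zenith_effective_deg=zenith,
        window=window,
        residuals_min=resid,
    )


# ---------------------------------------------------------------------------
# MCMC refinement


@dataclass
class EstellePriors:
    """Priors of the movement-refinement model.

    * deployment site anchoring the first (and optionally last) position,
    * calibrated twilight-error model,
    * gamma prior on great-circle flight speed between consecutive positions
      (km/h; default shape 2.2, rate 0.08, mean 27.5 km/h),
    * land mask raster (>= 0.5 land) forbidding stationary positions over
      water.
    """

    deployment: tuple[float, float]
    twilight_error: CalibrationModel
    speed_shape: float = 2.2
    speed_rate: float = 0.08
    land_mask: Raster | None = None
    arrival: tuple[float, float] | None = None

    def __post_init__(self):
        if self.speed_shape <= 0 or self.speed_rate <= 0:
            raise ValueError("gamma speed-prior parameters must be strictly positive")
        if self.land_mask is not None:
            v = self.land_mask.sample(*self.deployment)
            if not (np.isfinite(v) and v >= 0.5):
                raise ValueError("deployment location falls on water in the land mask")

    @property
    def prior_mean_speed_kmh(self) -> float:
        return self.speed_shape / self.speed_rate

    def speed_logpdf(self, v_kmh):
        v = np.maximum(np.asarray(v_kmh, dtype=float), 1e-3)
        return (self.speed_shape - 1.0) * np.log(v) - self.speed_rate * v


@dataclass
class McmcSchedule:
    burn_in: int = 250
    tuning_runs: int = 3
    tuning_iters: int = 300
    final_iters: int = 2000
    thin: int = 1
    target_acceptance: float = 0.23
    initial_scale_deg: float = 1.0


def _haversine_fast(lon1, lat1, lon2, lat2):
    lon1, lat1, lon2, lat2 = map(np.deg2rad, (lon1, lat1, lon2, lat2))
    a = (
        np.sin((lat2 - lat1) / 2) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2
    )
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


class _EstelleSampler:
    """Metropolis-within-Gibbs over one location per twilight event.

    Each twilight has its own location (two per day), so movement within a
    night is part of the model; events sharing a stopover group share a
    single location parameter.  Parameters are updated in an even/odd
    checkerboard so each half-sweep is a valid block update and fully
    vectorised.
    """

    def __init__(self, twilights, init_lonlat, group_ids, priors, anchor_last):
        self.priors = priors
        self.zenith = priors.twilight_error.zenith_deg

        group_ids = np.asarray(group_ids)
        groups = pd.unique(group_ids)
        self.n_params = len(groups)
        gmap = {g: i for i, g in enumerate(groups)}
        self.pos_param = np.array([gmap[g] for g in group_ids])

        times = pd.to_datetime(twilights["time"]).to_numpy().astype("datetime64[s]")
        hours = (times - times[0]) / np.timedelta64(3600, "s")
        self.param_hours = np.array(
            [hours[self.pos_param == i].mean() for i in range(self.n_params)]
        )
        self.dt_h = np.maximum(np.diff(self.param_hours), 0.5)

        decl, eqt = solar.solar_declination_eqtime(times)
        self.ev_param = self.pos_param
        self.ev_obs = _minutes_of_day(times)
        self.ev_decl = np.asarray(decl)
        self.ev_eq = np.asarray(eqt)
        self.ev_rising = twilights["type"].to_numpy() == "sunrise"

        counts = np.bincount(self.pos_param, minlength=self.n_params)
        self.stationary = counts > 1

        self.fixed = np.zeros(self.n_params, dtype=bool)
        self.fixed[0] = True
        if anchor_last:
            self.fixed[-1] = True

        # initial state: event positions averaged per parameter, anchors set
        init = np.empty((self.n_params, 2))
        init_lonlat = np.asarray(init_lonlat, dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for i in range(self.n_params):
                sel = self.pos_param == i
                init[i, 0] = np.nanmean(init_lonlat[sel, 0])
                init[i, 1] = np.nanmean(init_lonlat[sel, 1])
        for axis in (0, 1):
            finite = np.isfinite(init[:, axis])
            if not finite.all():
                init[:, axis] = np.interp(
                    np.arange(self.n_params), np.where(finite)[0], init[finite, axis]
                )
        init[0] = priors.deployment
        if anchor_last:
            init[-1] = priors.arrival if priors.arrival is not None else init[-1]
        self.state = init

    # -- log-target pieces ---------------------------------------------------

    def _twilight_loglik(self, lon, lat):
        """Summed twilight log-likelihood per parameter for given locations."""
        pl = lon[self.ev_param]
        pb = lat[self.ev_param]
        pred, absent = _predict_twilight_minutes(
            pl, pb, self.ev_decl, self.ev_eq, self.zenith, self.ev_rising
        )
        r = ((self.ev_obs - pred + 720.0) % 1440.0) - 720.0
        r = np.where(self.ev_rising, r, -r)
        lp = self.priors.twilight_error.logpdf(r)
        lp = np.where(absent, -50.0, lp)  # event absent at proposed latitude
        return np.bincount(self.ev_param, weights=lp, minlength=self.n_params)

    def _mask_ok(self, lon, lat):
        ok = np.ones(self.n_params, dtype=bool)
        if self.priors.land_mask is not None and self.stationary.any():
            v = self.priors.land_mask.sample(lon[self.stationary], lat[self.stationary])
            ok[self.stationary] = np.isfinite(v) & (v >= 0.5)
        return ok

    def _speed_terms(self, lon, lat):
        d = _haversine_fast(lon[:-1], lat[:-1], lon[1:], lat[1:])
        return self.priors.speed_logpdf(d / self.dt_h)

    def log_target(self, lon, lat):
        tw = self._twilight_loglik(lon, lat)
        sp = self._speed_terms(lon, lat)
        total = tw.sum() + sp.sum()
        if not self._mask_ok(lon, lat).all():
            return -np.inf
        return total

    # -- sampling ------------------------------------------------------------

    def _half_sweep(self, rng, scale, parity, acc_count=None):
        lon, lat = self.state[:, 0].copy(), self.state[:, 1].copy()
        upd = (np.arange(self.n_params) % 2 == parity) & ~self.fixed
        idx = np.where(upd)[0]
        if idx.size == 0:
            return 0, 0

        prop_lon = lon.copy()
        prop_lat = lat.copy()
        prop_lon[idx] = lon[idx] + rng.normal(0, scale[idx])
        # latitude is the poorly determined axis in light-level geolocation
        prop_lat[idx] = np.clip(lat[idx] + rng.normal(0, 2.0 * scale[idx]), -89.0, 89.0)

        # local target per parameter: own twilights + adjacent speed terms
        def local(lons, lats):
            tw = self._twilight_loglik(lons, lats)
            sp = self._speed_terms(lons, lats)
            out = tw[idx].astype(float)
            left = idx - 1
            out += np.where(left >= 0, sp[np.clip(left, 0, None)], 0.0)
            out += np.where(idx < self.n_params - 1, sp[np.clip(idx, 0, len(sp) - 1)], 0.0)
            mask_ok = self._mask_ok(lons, lats)
            out = np.where(mask_ok[idx], out, -np.inf)
            return out

        cur = local(lon, lat)
        new = local(prop_lon, prop_lat)
        accept = np.log(rng.uniform(size=idx.size)) < (new - cur)
        self.state[idx[accept], 0] = prop_lon[idx[accept]]
        self.state[idx[accept], 1] = prop_lat[idx[accept]]
        if acc_count is not None:
            acc_count[idx[accept]] += 1
        return int(accept.sum()), idx.size

    def run(self, rng, schedule: McmcSchedule):
        scale = np.full(self.n_params, schedule.initial_scale_deg)
        if not np.isfinite(self.log_target(self.state[:, 0], self.state[:, 1])):
            bad = np.where(~self._mask_ok(self.state[:, 0], self.state[:, 1]))[0]
            raise ValueError(
                f"non-finite initial log-target (mask violation at parameters {bad.tolist()})"
            )
        for _ in range(schedule.burn_in):
            self._half_sweep(rng, scale, 0)
            self._half_sweep(rng, scale, 1)
        for _ in range(schedule.tuning_runs):
            acc = np.zeros(self.n_params)
            for _ in range(schedule.tuning_iters):
                self._half_sweep(rng, scale, 0, acc_count=acc)
                self._half_sweep(rng, scale, 1, acc_count=acc)
            rate = acc / schedule.tuning_iters
            # per-parameter adaptation toward the target acceptance rate
            scale *= np.exp(2.0 * (rate - schedule.target_acceptance))
            scale = np.clip(scale, 1e-3, 20.0)
        samples = []
        for it in range(schedule.final_iters):
            self._half_sweep(rng, scale, 0)
            self._half_sweep(rng, scale, 1)
            if it % schedule.thin == 0:
                samples.append(self.state.copy())
        return np.array(samples)


def refine_positions_mcmc(
    initial: pd.DataFrame,
    priors: EstellePriors,
    twilights: pd.DataFrame,
    group_ids=None,
    schedule: McmcSchedule | None = None,
    rng: np.random.Generator | int | None = None,
    anchor_last: bool = False,
):
    """Refine the position sequence by MCMC under the movement model.

    The model places one location at every twilight event (two per day, the
    Estelle parameterisation); ``initial`` is the frame from
    :func:`threshold_positions` and seeds the chain.  ``group_ids`` assigns
    each twilight event to a location parameter (events of one stopover
    share a group and are treated as a single location); its length may also
    equal the number of twilight *pairs*, in which case it is expanded to
    events.  Returns ``(positions, samples)``: one row per twilight event
    with posterior mean lon/lat and 97.5% CI columns, and the posterior
    sample array of shape (n_samples, n_events, 2).
    """
    schedule = schedule or McmcSchedule()
    rng = np.random.default_rng(rng)
    tw = twilights[~twilights["excluded"]].reset_index(drop=True)
    n_ev = len(tw)
    n_pairs = len(initial)

    # event j sits in pairs (j-1, j); seed it with their mean position
    init_ev = np.full((n_ev, 2), np.nan)
    pl = initial["lon"].to_numpy(dtype=float)
    pb = initial["lat"].to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for j in range(n_ev):
            members = [k for k in (j - 1, j) if 0 <= k < n_pairs]
            init_ev[j, 0] = np.nanmean(pl[members])
            init_ev[j, 1] = np.nanmean(pb[members])

    if group_ids is None:
        group_ids = np.arange(n_ev)
    group_ids = np.asarray(group_ids)
    if len(group_ids) == n_pairs and n_pairs != n_ev:
        group_ids = group_ids[np.minimum(np.arange(n_ev), n_pairs - 1)]
    if len(group_ids) != n_ev:
        raise ValueError("group_ids must have one entry per twilight event (or per pair)")

    sampler = _EstelleSampler(tw, init_ev, group_ids, priors, anchor_last)
    param_samples = sampler.run(rng, schedule)

    pos_samples = param_samples[:, sampler.pos_param, :]
    out = pd.DataFrame(
        {
            "index": np.arange(n_ev),
            "date": tw["date"].to_numpy(),
            "type": tw["type"].to_numpy(),
            "time": pd.to_datetime(tw["time"]).to_numpy(),
            "group_id": group_ids,
            "lon_init": init_ev[:, 0],
            "lat_init": init_ev[:, 1],
        }
    )
    out["lon_mean"] = pos_samples[:, :, 0].mean(axis=0)
    out["lat_mean"] = pos_samples[:, :, 1].mean(axis=0)
    ci = credible_interval(pos_samples)
    for name, arr in ci.items():
        out[name] = arr
    return out, pos_samples


def day_roost_groups(twilights: pd.DataFrame) -> np.ndarray:
    """Event groups for a nocturnal migrant: stationary through the day.

    Each sunrise shares a location parameter with the following sunset (the
    bird roosts between them); movement happens across the night segments.
    Returns one group id per non-excluded twilight event.
    """
    tw = twilights[~twilights["excluded"]].reset_index(drop=True)
    types = tw["type"].to_numpy()
    groups = np.empty(len(tw), dtype=int)
    g = 0
    for i in range(len(tw)):
        if i > 0 and not (types[i - 1] == "sunrise" and types[i] == "sunset"):
            g += 1
        groups[i] = g
    return groups


def credible_interval(samples: np.ndarray, level: float = 0.975) -> dict[str, np.ndarray]:
    """Equal-tailed per-axis quantile box around position posterior samples.

    ``samples`` has shape (n_samples, n_positions, 2) or (n_samples, 2);
    the box bounds are the (1-level)/2 and (1+level)/2 sample quantiles.
    """
    s = np.asarray(samples, dtype=float)
    if s.ndim == 2:
        s = s[:, None, :]
    if s.shape[0] < 100:
        raise ValueError("need at least 100 posterior samples for a credible interval")
    lo, hi = (1.0 - level) / 2.0, (1.0 + level) / 2.0
    return {
        "lon_lo": np.squeeze(np.quantile(s[:, :, 0], lo, axis=0)),
        "lon_hi": np.squeeze(np.quantile(s[:, :, 0], hi, axis=0)),
        "lat_lo": np.squeeze(np.quantile(s[:, :, 1], lo, axis=0)),
        "lat_hi": np.squeeze(np.quantile(s[:, :, 1], hi, axis=0)),
    }


def daily_positions(positions: pd.DataFrame) -> pd.DataFrame:
    """Aggregate the two per-day estimates to one per date (midpoint, CI union)."""
    lon_col = "lon_mean" if "lon_mean" in positions else "lon"
    lat_col = "lat_mean" if "lat_mean" in positions else "lat"
    agg = {lon_col: "mean", lat_col: "mean"}
    for c in ("lon_lo", "lat_lo"):
        if c in positions:
            agg[c] = "min"
    for c in ("lon_hi", "lat_hi"):
        if c in positions:
            agg[c] = "max"
    out = positions.groupby("date").agg(agg).reset_index()
    return out.rename(columns={lon_col: "lon", lat_col: "lat"})
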