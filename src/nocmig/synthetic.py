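"""Synthetic migratory tracks, sensor streams, GPS fixes and rasters.

Ground truth for every downstream stage: a great-circle route through
waypoints travelled in nocturnal flight bouts whose per-period (dusk /
night / dawn) occurrence probabilities depend on the biome category under
the bird (ecological barrier vs hospitable), with stopover days, state-
dependent accelerometer activity, barometric pressure tracking flight
altitude through the standard atmosphere, light following solar elevation
with an exponential twilight tail and multiplicative shading noise, daily
00:00 UTC GPS fixes, and matching categorical biome / elevation / land-sea
rasters organised in latitude bands.

Once the route is completed the bird is sedentary (wintering), which
provides the stationary period required by Hill-Ekstrom calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as _date
from datetime import timedelta

import numpy as np
import pandas as pd

from . import solar
from .gpsmetrics import great_circle_km
from .isa import IsaParameters, altitude_to_pressure
from .rasters import Raster

__all__ = [
    "SimulationConfig",
    "TrueTrack",
    "Band",
    "simulate_track",
    "simulate_sensor_series",
    "simulate_gps_fixes",
    "make_rasters",
    "light_threshold_for_zenith",
]

INTERVAL_S = 300
PER_DAY = 86400 // INTERVAL_S


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic migration experiment.

    Activity states are well separated by default (means 1 / 15 / 60 logger
    units); migration probabilities encode the barrier effect structure:
    higher dusk migration probability and higher flight altitude inside
    barriers, night probabilities high everywhere, dawn intermediate.
    """

    seed: int = 0
    start_date: _date = _date(2018, 8, 5)
    n_days: int = 65
    route: tuple = ((5.5, 51.1), (5.0, 36.0), (15.0, 15.0), (25.0, -18.0))
    stopover_schedule: tuple = ()  # (start_day, duration_days) pairs
    state_means: tuple = (1.0, 15.0, 60.0)  # inactive, low, high
    state_sds: tuple = (0.5, 2.0, 5.0)
    dusk_migration_prob_barrier: float = 0.75
    dusk_migration_prob_hospitable: float = 0.40
    night_migration_prob_barrier: float = 0.85
    night_migration_prob_hospitable: float = 0.80
    dawn_migration_prob_barrier: float = 0.35
    dawn_migration_prob_hospitable: float = 0.30
    flight_altitude_barrier_m: float = 1600.0
    flight_altitude_hospitable_m: float = 800.0
    pressure_noise_hpa: float = 1.0
    light_shading_sd: float = 0.3  # lognormal sigma of the shading factor
    gps_altitude_noise_m: float = 10.0
    barrier_lat_bands: tuple = ((8.0, 32.0),)
    ground_elevation_m: float = 200.0
    flight_speed_kmh: float = 50.0
    max_flight_speed_kmh: float = 90.0
    light_scale: float = 1000.0
    light_floor: float = 1.0
    light_horizon_fraction: float = 0.05  # relative irradiance at elevation 0
    light_twilight_efold_deg: float = 3.0  # e-folding of log-light below horizon
    foraging_high_prob: float = 0.05
    foraging_low_prob: float = 0.55

    def __post_init__(self):
        probs = [
            self.dusk_migration_prob_barrier,
            self.dusk_migration_prob_hospitable,
            self.night_migration_prob_barrier,
            self.night_migration_prob_hospitable,
            self.dawn_migration_prob_barrier,
            self.dawn_migration_prob_hospitable,
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("migration probabilities must lie in [0, 1]")
        if not (self.state_means[0] < self.state_means[1] < self.state_means[2]):
            raise ValueError("state means must be strictly ordered inactive < low < high")
        if self.n_days < 2:
            raise ValueError("n_days must be >= 2")
        if len(self.route) < 2:
            raise ValueError("route needs at least 2 waypoints")

    def rng(self, stream: int) -> np.random.Generator:
        """Named substream so every generator is independently reproducible."""
        return np.random.default_rng([self.seed % (2**31), stream])

    def category_at(self, lat) -> np.ndarray:
        lat = np.asarray(lat, dtype=float)
        barrier = np.zeros(lat.shape, dtype=bool)
        for lo, hi in self.barrier_lat_bands:
            barrier |= (lat >= lo) & (lat < hi)
        out = np.where(barrier, "barrier", "hospitable")
        return out if out.ndim else out.item()

    def migration_prob(self, period: str, category: str) -> float:
        return getattr(self, f"{period}_migration_prob_{category}")

    def stopover_days(self) -> set[int]:
        days: set[int] = set()
        for start, dur in self.stopover_schedule:
            days.update(range(int(start), int(start) + int(dur)))
        return days


@dataclass
class TrueTrack:
    """Per-5-min ground truth: position, altitude, behavioural state, biome."""

    data: pd.DataFrame
    config: SimulationConfig

    def __len__(self):
        return len(self.data)


# ---------------------------------------------------------------------------
# route geometry


def _to_unit(lon, lat):
    lonr, latr = np.deg2rad(lon), np.deg2rad(lat)
    return np.array([np.cos(latr) * np.cos(lonr), np.cos(latr) * np.sin(lonr), np.sin(latr)])


def _from_unit(v):
    lon = np.rad2deg(np.arctan2(v[1], v[0]))
    lat = np.rad2deg(np.arcsin(np.clip(v[2], -1, 1)))
    return lon, lat


class _Route:
    """Great-circle polyline parameterised by distance along the route."""

    def __init__(self, waypoints):
        self.points = [np.asarray(p, dtype=float) for p in waypoints]
        legs = [great_circle_km(self.points[i], self.points[i + 1]) for i in range(len(self.points) - 1)]
        self.leg_km = np.asarray(legs)
        self.cum_km = np.concatenate([[0.0], np.cumsum(self.leg_km)])
        self.total_km = float(self.cum_km[-1])

    def position(self, dist_km):
        """(lon, lat) arrays at distances along the route (clamped to ends)."""
        d = np.clip(np.atleast_1d(np.asarray(dist_km, dtype=float)), 0.0, self.total_km)
        leg = np.clip(np.searchsorted(self.cum_km, d, side="right") - 1, 0, len(self.leg_km) - 1)
        frac = np.where(self.leg_km[leg] > 0, (d - self.cum_km[leg]) / self.leg_km[leg], 0.0)
        lons = np.empty_like(d)
        lats = np.empty_like(d)
        for li in np.unique(leg):
            sel = leg == li
            a = _to_unit(*self.points[li])
            b = _to_unit(*self.points[li + 1])
            omega = np.arccos(np.clip(np.dot(a, b), -1, 1))
            f = frac[sel]
            if omega < 1e-12:
                v = np.outer(np.ones_like(f), a).T
            else:
                v = (
                    np.sin((1 - f) * omega)[None, :] * a[:, None]
                    + np.sin(f * omega)[None, :] * b[:, None]
                ) / np.sin(omega)
            lons[sel], lats[sel] = _from_unit(v)
        if np.ndim(dist_km) == 0:
            return float(lons[0]), float(lats[0])
        return lons, lats


# ---------------------------------------------------------------------------
# track simulation


def simulate_track(config: SimulationConfig) -> TrueTrack:
    """Simulate the ground-truth track at 5-min resolution.

    Movement happens only in the migrating state, at ``flight_speed_kmh``
    along the route; whether a given dusk/night/dawn window is flown is a
    Bernoulli draw with the biome-category-dependent probability; migrating
    runs are extended to at least 60 min.  Stopover days never migrate, and
    after the final waypoint is reached the bird is sedentary.
    """
    rng = config.rng(1)
    route = _Route(config.route)
    n = config.n_days * PER_DAY
    t0 = np.datetime64(config.start_date.isoformat()) + np.timedelta64(0, "s")
    times = t0 + np.arange(n) * np.timedelta64(INTERVAL_S, "s")

    stopover = config.stopover_days()
    n_flight_days = max(config.n_days - len(stopover), 1)
    # feasibility: each leg gets flight days proportional to its share of the
    # route; ~8 h of flight per night is the plausible ceiling used here
    nightly_h = 8.0
    for i, leg in enumerate(route.leg_km):
        leg_days = max(n_flight_days * leg / max(route.total_km, 1e-9), 1e-9)
        required = leg / (leg_days * nightly_h)
        if required > config.max_flight_speed_kmh:
            raise ValueError(
                f"infeasible route: leg {i} ({config.route[i]} -> {config.route[i + 1]}, "
                f"{leg:.0f} km) requires {required:.0f} km/h > max "
                f"{config.max_flight_speed_kmh:.0f} km/h"
            )

    state = np.full(n, "inactive", dtype=object)
    migrating = np.zeros(n, dtype=bool)
    dist = np.zeros(n)
    period_arr = np.full(n, "day", dtype=object)

    d_now = 0.0
    step_km = config.flight_speed_kmh * INTERVAL_S / 3600.0
    min_run = 12  # 60 min at 5-min intervals

    for day in range(config.n_days):
        day_date = config.start_date + timedelta(days=day)
        i0 = day * PER_DAY
        lon0, lat0 = route.position(d_now)

        evs = {e.event: e for e in solar.solar_events(day_date, lon0, lat0)}
        nxt = {e.event: e for e in solar.solar_events(day_date + timedelta(days=1), lon0, lat0)}

        def idx_of(ts):
            if ts is None:
                return None
            k = int((np.datetime64(ts, "s") - t0) / np.timedelta64(INTERVAL_S, "s"))
            return min(max(k, 0), n)

        windows = []
        if evs["sunset"].occurs and evs["astro_dusk"].occurs:
            windows.append(("dusk", idx_of(evs["sunset"].time), idx_of(evs["astro_dusk"].time)))
        if evs["astro_dusk"].occurs and nxt["astro_dawn"].occurs:
            windows.append(("night", idx_of(evs["astro_dusk"].time), idx_of(nxt["astro_dawn"].time)))
        if nxt["astro_dawn"].occurs and nxt["sunrise"].occurs:
            windows.append(("dawn", idx_of(nxt["astro_dawn"].time), idx_of(nxt["sunrise"].time)))

        for name, a, b in windows:
            period_arr[a:b] = name

        arrived = d_now >= route.total_km - 1e-6
        fly_day = (day not in stopover) and not arrived

        for name, a, b in windows:
            if a is None or b is None or b <= a:
                continue
            cat = str(config.category_at(route.position(d_now)[1]))
            b_ext = min(max(b, a + min_run), n)
            # a window reaching into a stopover calendar day is never flown,
            # so stopover days contain no migrating interval at all
            last_day = (b_ext - 1) // PER_DAY
            clear = all(dd not in stopover for dd in range(day, last_day + 1))
            if fly_day and clear and rng.uniform() < config.migration_prob(name, cat):
                migrating[a:b_ext] = True
            # sequential movement through the window so position (and biome)
            # advances within the night
            for k in range(a, min(b, n)):
                if migrating[k] and d_now < route.total_km:
                    d_now = min(d_now + step_km, route.total_km)
                dist[k] = d_now
        # daytime intervals keep the current distance
        for k in range(i0, min(i0 + PER_DAY, n)):
            if dist[k] == 0.0 and k > 0:
                dist[k] = max(dist[k - 1], dist[k])
        arrived = d_now >= route.total_km - 1e-6

    dist = np.maximum.accumulate(dist)
    lons, lats = route.position(dist)

    # non-migrating behavioural states: roosting by day, some foraging in
    # crepuscular/night windows
    u = rng.uniform(size=n)
    is_day = period_arr == "day"
    p_low, p_high = config.foraging_low_prob, config.foraging_high_prob
    state[~is_day & ~migrating & (u < p_low)] = "low"
    state[~is_day & ~migrating & (u >= p_low) & (u < p_low + p_high)] = "high"
    state[is_day & (u < 0.1)] = "low"
    state[migrating] = "migrating"

    altitude = np.full(n, config.ground_elevation_m)
    cat_arr = config.category_at(lats)
    flight_alt = np.where(
        cat_arr == "barrier", config.flight_altitude_barrier_m, config.flight_altitude_hospitable_m
    )
    altitude[migrating] = config.ground_elevation_m + flight_alt[migrating]

    data = pd.DataFrame(
        {
            "timestamp": times.astype("datetime64[s]"),
            "lon": lons,
            "lat": lats,
            "altitude_asl_m": altitude,
            "state": state,
            "biome_category": cat_arr,
            "period": period_arr,
            "day_index": np.repeat(np.arange(config.n_days), PER_DAY),
        }
    )
    return TrueTrack(data=data, config=config)


# ---------------------------------------------------------------------------
# sensors


def _light_fraction(elev_deg, config: SimulationConfig):
    """Relative irradiance vs solar elevation: sine above the horizon with a
    continuous exponential twilight tail below it (log-light linear in sun
    elevation), which is what makes threshold crossings at zenith > 90 deg
    observable."""
    e = np.asarray(elev_deg, dtype=float)
    c = config.light_horizon_fraction
    above = c + (1.0 - c) * np.sin(np.deg2rad(np.maximum(e, 0.0)))
    below = c * np.exp(np.minimum(e, 0.0) / config.light_twilight_efold_deg)
    return np.where(e >= 0.0, above, below)


def light_threshold_for_zenith(zenith_deg: float, config: SimulationConfig) -> float:
    """Light level at which the noise-free trace crosses when the sun is at
    the given zenith angle — the threshold that calibrates to that zenith."""
    return float(config.light_scale * _light_fraction(90.0 - zenith_deg, config))


def simulate_sensor_series(track: TrueTrack, config: SimulationConfig | None = None):
    """Sensor records (activity, pressure, light, temperature) for a track.

    Activity draws from the state's normal distribution (migrating uses the
    high-activity distribution); pressure is the ISA inverse of true altitude
    plus Gaussian noise; light follows solar elevation at the true position
    with one multiplicative lognormal shading factor per half solar day
    (shading varies on cloud/vegetation timescales, not per 5-min sample)
    and a darkness floor.
    """
    from .activity import SensorSeries

    config = config or track.config
    if not len(track.data):
        raise ValueError("empty track")
    rng = config.rng(2)
    df = track.data
    n = len(df)

    mean_map = dict(zip(("inactive", "low", "high"), config.state_means))
    sd_map = dict(zip(("inactive", "low", "high"), config.state_sds))
    mean_map["migrating"], sd_map["migrating"] = config.state_means[2], config.state_sds[2]
    means = df["state"].map(mean_map).to_numpy(dtype=float)
    sds = df["state"].map(sd_map).to_numpy(dtype=float)
    activity = np.maximum(means + rng.normal(0.0, 1.0, n) * sds, 0.0)

    pressure = altitude_to_pressure(df["altitude_asl_m"].to_numpy(), IsaParameters())
    pressure = pressure + rng.normal(0.0, config.pressure_noise_hpa, n)

    t64 = df["timestamp"].to_numpy().astype("datetime64[s]")
    elev = solar.solar_elevation(t64, df["lon"].to_numpy(), df["lat"].to_numpy())
    frac = _light_fraction(elev, config)
    # one shading factor per half solar day (indexed by local solar half-day)
    local_hours = (
        (t64 - t64[0]) / np.timedelta64(3600, "s") + df["lon"].to_numpy() / 15.0
    )
    halfday = np.floor(local_hours / 12.0).astype(int)
    halfday -= halfday.min()
    shading = np.exp(-np.abs(rng.normal(0.0, config.light_shading_sd, halfday.max() + 1)))
    light = np.maximum(config.light_scale * frac * shading[halfday], config.light_floor)

    temperature = 25.0 - 0.0065 * df["altitude_asl_m"].to_numpy() + 5.0 * np.sin(
        2 * np.pi * (local_hours % 24.0 - 9.0) / 24.0
    )

    data = pd.DataFrame(
        {
            "timestamp": df["timestamp"].to_numpy(),
            "activity": activity,
            "pressure_hpa": pressure,
            "light": light,
            "temperature_c": temperature,
        }
    )
    return SensorSeries(individual_id=f"sim{config.seed}", data=data)


def simulate_gps_fixes(track: TrueTrack, config: SimulationConfig | None = None) -> pd.DataFrame:
    """One fix per 00:00 UTC at the true position, with altitude noise."""
    config = config or track.config
    rng = config.rng(3)
    df = track.data
    t = pd.to_datetime(df["timestamp"])
    at_midnight = (t.dt.hour == 0) & (t.dt.minute == 0) & (t.dt.second == 0)
    sel = df[at_midnight]
    if not len(sel):
        raise ValueError("track spans no 00:00 UTC instant")
    return pd.DataFrame(
        {
            "timestamp": sel["timestamp"].to_numpy(),
            "lon": sel["lon"].to_numpy(),
            "lat": sel["lat"].to_numpy(),
            "altitude_asl_m": sel["altitude_asl_m"].to_numpy()
            + rng.normal(0.0, config.gps_altitude_noise_m, len(sel)),
        }
    )


def simulate_twilights(
    track: TrueTrack,
    zenith_deg: float = 96.0,
    delay_scale_min: float = 3.5,
    delay_shape: float = 0.6,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Twilight events observed at the moving true position, with lognormal
    shading delays (dawn crossings delayed, dusk crossings advanced).

    Bypasses the light trace: event times are solved at the position the bird
    occupies around each event, so this is the model-consistent observation
    process for validating calibration and MCMC refinement directly.
    """
    config = track.config
    rng = np.random.default_rng(config.seed + 1000 if rng is None else rng)
    df = track.data
    t64 = df["timestamp"].to_numpy().astype("datetime64[s]")
    rows = []
    for day in range(config.n_days):
        d = config.start_date + timedelta(days=day)
        day64 = np.datetime64(d.isoformat())
        for rising, typ in ((True, "sunrise"), (False, "sunset")):
            # position at the approximate event time (two fixed-point passes)
            k = np.searchsorted(t64, day64.astype("datetime64[s]") + np.timedelta64(12, "h"))
            k = min(k, len(df) - 1)
            for _ in range(2):
                lon, lat = df["lon"].iloc[k], df["lat"].iloc[k]
                m = float(solar.event_time_minutes(day64, lon, lat, zenith_deg, rising))
                if np.isnan(m):
                    break
                when = day64.astype("datetime64[s]") + np.timedelta64(int(m * 60), "s")
                k = min(np.searchsorted(t64, when), len(df) - 1)
            if np.isnan(m):
                continue
            delay = rng.lognormal(np.log(delay_scale_min), delay_shape)
            m_obs = m + delay if rising else m - delay
            when = pd.Timestamp(day64.astype("datetime64[s]")) + pd.Timedelta(minutes=m_obs)
            rows.append({"date": d, "type": typ, "time": when, "excluded": False})
    out = pd.DataFrame(rows).sort_values("time").reset_index(drop=True)
    # enforce alternation (a delayed dawn can in principle leapfrog a dusk)
    keep = [0]
    for i in range(1, len(out)):
        if out["type"].iloc[i] != out["type"].iloc[keep[-1]]:
            keep.append(i)
    return out.iloc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# rasters


@dataclass(frozen=True)
class Band:
    lat_min: float
    lat_max: float
    biome_code: int
    category: str
    elevation_m: float = 200.0


def default_band_spec(config: SimulationConfig, lat_min: float, lat_max: float) -> list[Band]:
    """Latitude bands consistent with the config's barrier bands: barriers as
    Desert and Xeric Shrubland (13), hospitable as tropical savannah (7)."""
    edges = sorted({lat_min, lat_max, *(b for band in config.barrier_lat_bands for b in band)})
    edges = [e for e in edges if lat_min <= e <= lat_max]
    bands = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mid = 0.5 * (lo + hi)
        barrier = str(config.category_at(mid)) == "barrier"
        bands.append(
            Band(lo, hi, 13 if barrier else 7, "barrier" if barrier else "hospitable",
                 config.ground_elevation_m)
        )
    return bands


def make_rasters(
    extent: tuple[float, float, float, float],
    cell_size: float,
    band_spec: list[Band],
    ocean_rects: tuple = (),
) -> tuple[Raster, Raster, Raster]:
    """(biome, elevation, land/sea) rasters on a shared grid.

    ``extent`` is (west, east, south, north); bands are latitude intervals
    [lat_min, lat_max) and must not overlap; ``ocean_rects`` are
    (west, east, south, north) rectangles marked as sea (0) in the mask.
    """
    west, east, south, north = extent
    ncols = (east - west) / cell_size
    nrows = (north - south) / cell_size
    if abs(ncols - round(ncols)) > 1e-9 or abs(nrows - round(nrows)) > 1e-9:
        raise ValueError("cell_size does not tile the extent")
    ncols, nrows = int(round(ncols)), int(round(nrows))

    spans = sorted((b.lat_min, b.lat_max) for b in band_spec)
    for (a0, a1), (b0, b1) in zip(spans[:-1], spans[1:]):
        if b0 < a1 - 1e-12:
            raise ValueError("overlapping latitude bands in band_spec")

    lat_centers = south + (nrows - np.arange(nrows) - 0.5) * cell_size
    biome = np.full((nrows, ncols), -9999, dtype=int)
    dem = np.full((nrows, ncols), -9999.0)
    for b in band_spec:
        rows = (lat_centers >= b.lat_min) & (lat_centers < b.lat_max)
        biome[rows, :] = b.biome_code
        dem[rows, :] = b.elevation_m

    landsea = np.ones((nrows, ncols), dtype=int)
    lon_centers = west + (np.arange(ncols) + 0.5) * cell_size
    for w, e, s, nth in ocean_rects:
        cols = (lon_centers >= w) & (lon_centers < e)
        rows = (lat_centers >= s) & (lat_centers < nth)
        landsea[np.ix_(rows, cols)] = 0

    mk = lambda vals, nod: Raster(vals, west, south, cell_size, nodata=nod)
    return mk(biome, -9999), mk(dem, -9999.0), mk(landsea, -9999)
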