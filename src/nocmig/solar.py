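"""Solar geometry: sun elevation, twilight events and day-period classification.

Implements the NOAA solar-calculator algorithm (Meeus-style truncated series)
for the apparent position of the sun, accurate to well under 0.1 degree of
elevation for the years around 2000-2050, which is far below the positional
error of light-level geolocation.

Period definitions for a crepuscular/nocturnal migrant:

* ``day``   — sun above the sunrise/sunset horizon (elevation > -0.833 deg,
  i.e. standard refraction plus solar radius),
* ``dusk``  — between sunset and astronomical dusk (sun descending,
  elevation in (-18, -0.833]),
* ``night`` — sun below -18 deg (astronomical night),
* ``dawn``  — between astronomical dawn and sunrise (sun ascending).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date as _date
from datetime import datetime, timezone
from typing import Iterable

import numpy as np

__all__ = [
    "SolarEvent",
    "solar_elevation",
    "solar_declination_eqtime",
    "solar_events",
    "classify_period",
    "SUNRISE_SUNSET_ZENITH",
    "ASTRONOMICAL_ZENITH",
]

#: zenith angle of sunrise/sunset: 90 deg + 0.567 refraction + 0.267 solar radius
SUNRISE_SUNSET_ZENITH = 90.833
#: zenith angle of astronomical dawn/dusk (sun 18 deg below the horizon)
ASTRONOMICAL_ZENITH = 108.0

_EPOCH_J2000 = np.datetime64("2000-01-01T12:00:00", "s")


def _to_datetime64(t) -> np.ndarray:
    """Coerce scalars/arrays of timestamps to datetime64[s] (UTC assumed)."""
    if isinstance(t, datetime):
        if t.tzinfo is not None:
            t = t.astimezone(timezone.utc).replace(tzinfo=None)
        return np.datetime64(t, "s")
    return np.asarray(t, dtype="datetime64[s]")


def _julian_century(t64: np.ndarray) -> np.ndarray:
    days = (t64 - _EPOCH_J2000) / np.timedelta64(86400, "s")
    return days / 36525.0


def solar_declination_eqtime(t):
    """Solar declination (deg) and equation of time (minutes) at UTC time ``t``.

    Returns ``(declination_deg, eqtime_min)``; vectorised over ``t``.
    """
    T = _julian_century(_to_datetime64(t))
    rad = np.deg2rad

    L0 = np.remainder(280.46646 + T * (36000.76983 + 0.0003032 * T), 360.0)
    M = 357.52911 + T * (35999.05029 - 0.0001537 * T)
    e = 0.016708634 - T * (0.000042037 + 0.0000001267 * T)
    Mr = rad(M)
    C = (
        np.sin(Mr) * (1.914602 - T * (0.004817 + 0.000014 * T))
        + np.sin(2 * Mr) * (0.019993 - 0.000101 * T)
        + np.sin(3 * Mr) * 0.000289
    )
    true_long = L0 + C
    omega = rad(125.04 - 1934.136 * T)
    lam = rad(true_long - 0.00569 - 0.00478 * np.sin(omega))

    eps0 = 23.0 + (26.0 + (21.448 - T * (46.815 + T * (0.00059 - T * 0.001813))) / 60.0) / 60.0
    eps = rad(eps0 + 0.00256 * np.cos(omega))

    decl = np.arcsin(np.sin(eps) * np.sin(lam))

    y = np.tan(eps / 2.0) ** 2
    L0r = rad(L0)
    eqtime = 4.0 * np.rad2deg(
        y * np.sin(2 * L0r)
        - 2.0 * e * np.sin(Mr)
        + 4.0 * e * y * np.sin(Mr) * np.cos(2 * L0r)
        - 0.5 * y * y * np.sin(4 * L0r)
        - 1.25 * e * e * np.sin(2 * Mr)
    )
    return np.rad2deg(decl), eqtime


def solar_elevation(t, lon, lat):
    """Apparent solar elevation angle (deg) at UTC time ``t`` and position.

    ``lon`` east-positive, ``lat`` north-positive, degrees.  Vectorised.
    No refraction correction is applied here; the period thresholds carry it.
    """
    lat = np.asarray(lat, dtype=float)
    if np.any(np.abs(lat) > 90):
        raise ValueError("latitude out of range [-90, 90]")
    t64 = _to_datetime64(t)
    decl, eqtime = solar_declination_eqtime(t64)

    secs = (t64 - t64.astype("datetime64[D]").astype("datetime64[s]")) / np.timedelta64(1, "s")
    tst = secs / 60.0 + eqtime + 4.0 * np.asarray(lon, dtype=float)  # true solar time, min
    ha = np.deg2rad(tst / 4.0 - 180.0)

    latr = np.deg2rad(lat)
    declr = np.deg2rad(decl)
    cos_zen = np.sin(latr) * np.sin(declr) + np.cos(latr) * np.cos(declr) * np.cos(ha)
    return 90.0 - np.rad2deg(np.arccos(np.clip(cos_zen, -1.0, 1.0)))


@dataclass(frozen=True)
class SolarEvent:
    """One solar event on one date at one position.

    ``time`` is ``None`` when the event does not occur at that latitude/date
    (midnight sun or polar night); ``occurs`` makes the marker explicit.
    """

    date: _date
    event: str  # sunrise | sunset | astro_dawn | astro_dusk
    time: datetime | None
    zenith_deg: float

    @property
    def occurs(self) -> bool:
        return self.time is not None


def _event_minutes(day64: np.ndarray, lon, lat, zenith_deg, rising: bool):
    """UTC minutes-of-day of a threshold crossing; NaN where it never occurs.

    Two fixed-point iterations refine declination/eqtime at the event time.
    Vectorised over ``day64`` / ``lon`` / ``lat``.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    latr = np.deg2rad(lat)
    cz = np.cos(np.deg2rad(zenith_deg))

    minutes = np.full(np.broadcast(day64, lon, lat).shape, 720.0 - 4.0 * lon)
    for _ in range(3):
        t_guess = day64.astype("datetime64[s]") + (minutes * 60).astype("timedelta64[s]")
        decl, eqtime = solar_declination_eqtime(t_guess)
        declr = np.deg2rad(decl)
        cos_ha = (cz - np.sin(latr) * np.sin(declr)) / (np.cos(latr) * np.cos(declr))
        with np.errstate(invalid="ignore"):
            ha = np.rad2deg(np.arccos(np.clip(cos_ha, -1.0, 1.0)))
        ha = np.where(np.abs(cos_ha) > 1.0, np.nan, ha)
        sign = -1.0 if rising else 1.0
        minutes = 720.0 - 4.0 * lon - eqtime + sign * 4.0 * ha
    return minutes


def solar_events(date, lon, lat) -> list[SolarEvent]:
    """Sunrise/sunset and astronomical dawn/dusk for one date and position.

    Sunrise/sunset use zenith 90.833 deg; astronomical twilight 108 deg.
    Events that do not occur (high latitude) are returned with ``time=None``.
    """
    if isinstance(date, datetime):
        date = date.date()
    day64 = np.datetime64(date.isoformat())
    out = []
    for name, zen, rising in (
        ("astro_dawn", ASTRONOMICAL_ZENITH, True),
        ("sunrise", SUNRISE_SUNSET_ZENITH, True),
        ("sunset", SUNRISE_SUNSET_ZENITH, False),
        ("astro_dusk", ASTRONOMICAL_ZENITH, False),
    ):
        m = float(_event_minutes(day64, lon, lat, zen, rising))
        if np.isnan(m):
            out.append(SolarEvent(date, name, None, zen))
        else:
            t = (day64.astype("datetime64[s]") + np.timedelta64(int(round(m * 60)), "s")).item()
            out.append(SolarEvent(date, name, t, zen))
    return out


def event_time_minutes(day64, lon, lat, zenith_deg, rising):
    """Vectorised raw event solver (UTC minutes of day, NaN if absent).

    Exposed for the geolocation module, which needs many twilight-time
    predictions per MCMC sweep.
    """
    return _event_minutes(np.asarray(day64, dtype="datetime64[D]"), lon, lat, zenith_deg, rising)


def classify_period(t, lon, lat):
    """Label timestamps day / dusk / night / dawn at a position. Vectorised.

    Dusk vs dawn in the twilight band is decided by the sign of the elevation
    change over +/-5 min; at latitudes where astronomical twilight never ends
    the band is split at the local solar midnight implicit in that sign.
    """
    t64 = _to_datetime64(t)
    elev = solar_elevation(t64, lon, lat)
    five = np.timedelta64(300, "s")
    rising = solar_elevation(t64 + five, lon, lat) > solar_elevation(t64 - five, lon, lat)

    labels = np.where(
        elev > -0.833,
        "day",
        np.where(elev <= -18.0, "night", np.where(rising, "dawn", "dusk")),
    )
    if labels.ndim == 0:
        return labels.item()
    return labels


def night_window(date, lon, lat) -> tuple[datetime, datetime]:
    """Sunset on ``date`` to the next sunrise, the 'logger night' of that date.

    Falls back to local solar 18:00-06:00 when sunset/sunrise do not occur.
    """
    evs = {e.event: e for e in solar_events(date, lon, lat)}
    nxt = {e.event: e for e in solar_events(_next_day(date), lon, lat)}
    if evs["sunset"].occurs and nxt["sunrise"].occurs:
        return evs["sunset"].time, nxt["sunrise"].time
    base = datetime.fromisoformat(f"{date.isoformat()}T18:00:00")
    off = np.timedelta64(int(-4 * 60 * float(np.asarray(lon))), "s").item()
    return base + off, base + off + (datetime.min.replace(hour=12) - datetime.min)


def _next_day(d: _date) -> _date:
    return (np.datetime64(d.isoformat()) + np.timedelta64(1, "D")).item()
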