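"""Daily travel metrics from archival GPS fixes taken at 00:00 GMT.

Daily travel speed is the great-circle distance between consecutive fixes per
24 h; flight altitude above ground subtracts terrain elevation from the fix
altitude.  Days on which directional movement was interrupted are removed so
that only travel segments enter the biome comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rasters import Raster

__all__ = [
    "EARTH_RADIUS_KM",
    "great_circle_km",
    "daily_travel_speed",
    "retain_travel_segments",
    "altitude_above_ground",
    "recovery_rate_percent",
]

EARTH_RADIUS_KM = 6371.0088  # IUGG mean Earth radius


def great_circle_km(p1, p2):
    """Haversine distance in km between (lon, lat) points (deg). Vectorised."""
    lon1, lat1 = np.deg2rad(np.asarray(p1, dtype=float)).T
    lon2, lat2 = np.deg2rad(np.asarray(p2, dtype=float)).T
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return float(d) if np.ndim(d) == 0 else d


def daily_travel_speed(fixes: pd.DataFrame) -> pd.DataFrame:
    """Per-day travel speed (km/day) from consecutive GPS fixes.

    ``fixes`` columns: timestamp, lon, lat, altitude_asl_m.  Speed on a day
    is the distance from the previous fix; when the gap deviates from 24 h by
    more than 5 min the distance is normalised to a km-per-24 h rate and the
    record flagged ``interpolated_denominator``; skipped days yield missing
    records (distances are never pooled over multi-day gaps).
    """
    if fixes["timestamp"].duplicated().any():
        raise ValueError("duplicate GPS timestamps")
    f = fixes.sort_values("timestamp").reset_index(drop=True)
    t = pd.to_datetime(f["timestamp"])
    pts = f[["lon", "lat"]].to_numpy(dtype=float)
    rows = []
    for i in range(1, len(f)):
        gap_h = (t[i] - t[i - 1]) / pd.Timedelta(hours=1)
        dist = great_circle_km(pts[i - 1], pts[i])
        irregular = abs(gap_h - 24.0) > 5.0 / 60.0
        speed = dist * 24.0 / gap_h if irregular else dist
        # one missing record per fully skipped day inside the gap
        for k in range(1, int(round(gap_h / 24.0))):
            rows.append(
                {
                    "date": (t[i - 1] + pd.Timedelta(days=k)).date(),
                    "speed_km_per_day": np.nan,
                    "lon": np.nan,
                    "lat": np.nan,
                    "altitude_asl_m": np.nan,
                    "interpolated_denominator": False,
                }
            )
        rows.append(
            {
                "date": t[i].date(),
                "speed_km_per_day": speed,
                "lon": pts[i, 0],
                "lat": pts[i, 1],
                "altitude_asl_m": float(f["altitude_asl_m"].iloc[i]),
                "interpolated_denominator": irregular,
            }
        )
    return pd.DataFrame(rows)


def retain_travel_segments(records: pd.DataFrame, min_daily_km: float = 25.0) -> pd.DataFrame:
    """Flag travel-segment days: speed >= ``min_daily_km``.

    Days below the threshold (or missing) are interruptions and are flagged
    out of segment; the operation is idempotent.
    """
    out = records.copy()
    speed = out["speed_km_per_day"].to_numpy(dtype=float)
    out["in_travel_segment"] = np.isfinite(speed) & (speed >= min_daily_km)
    return out


def altitude_above_ground(fixes: pd.DataFrame, dem: Raster) -> pd.DataFrame:
    """Altitude above ground level = fix ASL minus nearest-cell terrain.

    Negative AGL (fix below local terrain, typical of a bird on the ground
    plus DEM coarseness) is clamped to 0 and flagged; fixes outside the DEM
    or over NODATA yield missing values.
    """
    out = fixes.copy()
    terrain = dem.sample(out["lon"].to_numpy(dtype=float), out["lat"].to_numpy(dtype=float))
    agl = out["altitude_asl_m"].to_numpy(dtype=float) - terrain
    out["terrain_m"] = terrain
    out["agl_clamped"] = np.isfinite(agl) & (agl < 0)
    out["altitude_agl_m"] = np.where(np.isfinite(agl), np.maximum(agl, 0.0), np.nan)
    return out


def recovery_rate_percent(n_recovered: int, n_deployed: int) -> float:
    """Tag recovery rate as a percentage (one decimal)."""
    if n_deployed <= 0 or n_recovered < 0 or n_recovered > n_deployed:
        raise ValueError("invalid recovery counts")
    return round(100.0 * n_recovered / n_deployed, 1)
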