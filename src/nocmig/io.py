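"""CSV/GeoJSON dialects shared across the pipeline.

All timestamps are written as ISO-8601 UTC with an explicit ``Z`` suffix and
rejected on read if the zone is missing; longitudes are decimal degrees in
[-180, 180), WGS84.  Every artifact written by the pipeline starts with
``#``-comment header lines recording package version, config hash and seed,
which readers skip transparently.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd


def _format_timestamps(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in ("timestamp", "time", "time_mid", "time_first", "time_second"):
        if col in out.columns:
            t = pd.to_datetime(out[col])
            if getattr(t.dt, "tz", None) is not None:
                t = t.dt.tz_convert("UTC").dt.tz_localize(None)
            out[col] = t.dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    return out


def write_csv(df: pd.DataFrame, path, meta: dict | None = None) -> Path:
    """Write a frame with ``#`` metadata header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as f:
        for k, v in (meta or {}).items():
            f.write(f"# {k}: {v}\n")
        _format_timestamps(df).to_csv(f, index=False)
    return path


def read_csv(path, timestamp_columns: tuple[str, ...] = ("timestamp", "time")) -> pd.DataFrame:
    """Read a pipeline CSV; timestamp columns must carry an explicit zone."""
    df = pd.read_csv(path, comment="#")
    for col in timestamp_columns:
        if col not in df.columns:
            continue
        raw = df[col].astype(str)
        zoned = raw.str.endswith("Z") | raw.str.contains(r"[+-]\d{2}:?\d{2}$", regex=True)
        if not zoned.all():
            bad = int(np.argmax(~zoned.to_numpy()))
            raise ValueError(
                f"{path}: timestamp without timezone in column {col!r}, line {bad + 2}"
            )
        df[col] = pd.to_datetime(raw, utc=True).dt.tz_localize(None)
    return df


def read_sensor_csv(path, individual_id: str | None = None):
    """Read a multi-sensor logger CSV into a SensorSeries."""
    from .activity import SensorSeries

    df = read_csv(path)
    required = {"timestamp", "activity", "pressure_hpa", "light"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: sensor CSV missing columns {sorted(missing)}")
    return SensorSeries(individual_id=individual_id or Path(path).stem, data=df)


def read_gps_csv(path) -> pd.DataFrame:
    df = read_csv(path)
    required = {"timestamp", "lon", "lat", "altitude_asl_m"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: GPS CSV missing columns {sorted(missing)}")
    if (df["lon"].abs() > 180).any() or (df["lat"].abs() > 90).any():
        raise ValueError(f"{path}: coordinates out of range")
    df["lon"] = (df["lon"] + 180.0) % 360.0 - 180.0
    return df


def write_geojson_track(lons, lats, path, properties: dict | None = None) -> Path:
    """Write a track as a GeoJSON LineString feature."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    feature = {
        "type": "Feature",
        "properties": properties or {},
        "geometry": {
            "type": "LineString",
            "coordinates": [
                [round(float(x), 6), round(float(y), 6)]
                for x, y in zip(np.asarray(lons), np.asarray(lats))
                if np.isfinite(x) and np.isfinite(y)
            ],
        },
    }
    path.write_text(json.dumps({"type": "FeatureCollection", "features": [feature]}, indent=1))
    return path
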