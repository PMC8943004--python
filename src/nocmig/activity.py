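"""Accelerometer activity classification, flight-bout and stopover detection.

The activity index of a multi-sensor tag is the per-interval sum of absolute
z-axis acceleration differences, which separates flapping flight from ground
behaviour.  Values are classified per individual into three states
(inactive < low < high) by one-dimensional k-means, migratory flight bouts
are maximal runs of uninterrupted high activity of at least 60 min, and
stopovers are runs of nights containing no flight bout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import date as _date
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SensorSeries",
    "FlightBout",
    "Stopover",
    "classify_activity",
    "detect_flight_bouts",
    "delineate_stopovers",
    "derive_binary_variables",
]

STATES = ("inactive", "low", "high")


@dataclass
class SensorSeries:
    """Aligned 5-min logger records for one individual.

    ``data`` columns: timestamp (UTC, tz-naive), activity, pressure_hpa,
    light, temperature_c — any sensor column may be missing/NaN.
    """

    individual_id: str
    data: pd.DataFrame
    nominal_interval_s: float = 300.0

    def __post_init__(self):
        t = pd.to_datetime(self.data["timestamp"])
        if not t.is_monotonic_increasing or t.duplicated().any():
            raise ValueError("timestamps must be strictly increasing")
        self.data = self.data.reset_index(drop=True)

    def gap_flags(self) -> np.ndarray:
        """True where the step *to* this record exceeds the nominal interval."""
        t = pd.to_datetime(self.data["timestamp"]).to_numpy()
        dt = np.diff(t) / np.timedelta64(1, "s")
        return np.concatenate([[False], dt > 1.5 * self.nominal_interval_s])


@dataclass(frozen=True)
class FlightBout:
    start: pd.Timestamp
    end: pd.Timestamp
    n_intervals: int

    @property
    def duration_min(self) -> float:
        return self.n_intervals * 5.0


@dataclass(frozen=True)
class Stopover:
    start_date: _date
    end_date: _date

    @property
    def n_days(self) -> int:
        return (pd.Timestamp(self.end_date) - pd.Timestamp(self.start_date)).days + 1


def _kmeans_1d(values: np.ndarray, k: int, tol: float = 1e-10, max_iter: int = 500):
    """Deterministic 1-D Lloyd k-means with quantile initialisation.

    Centroids start at the 1/(2k), 3/(2k), ... quantiles, so identical data
    always yields identical clusters — no random restarts.
    """
    qs = (2 * np.arange(k) + 1) / (2 * k)
    centroids = np.quantile(values, qs)
    for _ in range(max_iter):
        edges = (centroids[:-1] + centroids[1:]) / 2.0
        assign = np.searchsorted(edges, values)
        new = np.array(
            [values[assign == j].mean() if np.any(assign == j) else centroids[j] for j in range(k)]
        )
        if np.max(np.abs(new - centroids)) < tol:
            centroids = new
            break
        centroids = new
    order = np.argsort(centroids)
    rank = np.empty(k, dtype=int)
    rank[order] = np.arange(k)
    return rank[assign], centroids[order]


def classify_activity(series: SensorSeries | Sequence[float], k: int = 3) -> pd.DataFrame:
    """Classify activity values into ``k`` ordered states per individual.

    Returns a frame with columns ``timestamp`` (if available), ``state``
    (categorical inactive/low/high for k=3) and ``state_rank`` (0..k-1).
    Raises on fewer than ``k`` distinct values (degenerate distribution).
    """
    if isinstance(series, SensorSeries):
        values = series.data["activity"].to_numpy(dtype=float)
        ts = pd.to_datetime(series.data["timestamp"])
    else:
        values = np.asarray(series, dtype=float)
        ts = None
    finite = np.isfinite(values)
    if np.unique(values[finite]).size < k:
        raise ValueError("degenerate activity distribution: fewer than k distinct values")

    rank = np.full(values.shape, -1, dtype=int)
    rank[finite], _ = _kmeans_1d(values[finite], k)

    names = STATES if k == 3 else tuple(f"state{j}" for j in range(k))
    state = pd.array([names[r] if r >= 0 else None for r in rank], dtype="object")
    out = pd.DataFrame({"state": state, "state_rank": rank})
    if ts is not None:
        out.insert(0, "timestamp", ts.to_numpy())
    return out


def detect_flight_bouts(
    labels: pd.DataFrame,
    min_duration_min: float = 60.0,
    interval_s: float = 300.0,
    gap_tolerance: int = 0,
) -> list[FlightBout]:
    """Maximal runs of consecutive high-state intervals lasting >= 60 min.

    "Uninterrupted" is strict: any non-high interval (or a recording gap)
    breaks a run; ``gap_tolerance`` > 0 relaxes that to allow that many
    interrupting intervals inside a run.
    """
    high = (labels["state"].to_numpy() == "high").astype(int)
    t = pd.to_datetime(labels["timestamp"]).to_numpy()
    dt = np.diff(t) / np.timedelta64(1, "s")
    gap_before = np.concatenate([[False], dt > 1.5 * interval_s])

    min_n = int(np.ceil(min_duration_min * 60.0 / interval_s))
    bouts: list[FlightBout] = []
    i, n = 0, len(high)
    while i < n:
        if not high[i]:
            i += 1
            continue
        j, misses = i, 0
        last_high = i
        while j + 1 < n and not gap_before[j + 1]:
            if high[j + 1]:
                j += 1
                last_high = j
            elif misses < gap_tolerance:
                j += 1
                misses += 1
            else:
                break
        j = last_high
        count = int(high[i : j + 1].sum()) if gap_tolerance else (j - i + 1)
        if j - i + 1 >= min_n and count >= min_n - gap_tolerance:
            bouts.append(
                FlightBout(
                    start=pd.Timestamp(t[i]),
                    end=pd.Timestamp(t[j]) + pd.Timedelta(seconds=interval_s),
                    n_intervals=j - i + 1,
                )
            )
        i = j + 1
    return bouts


def delineate_stopovers(
    bouts: list[FlightBout],
    span: tuple[_date, _date],
    night_window_fn: Callable[[_date], tuple[pd.Timestamp, pd.Timestamp]],
) -> list[Stopover]:
    """Merge consecutive bout-free nights into stopover periods.

    A night is attributed to the date of its sunset (actogram convention for
    a nocturnal migrant); ``night_window_fn(date)`` returns that night's
    (sunset, sunrise) window.  Nights within ``span`` whose window overlaps
    no bout become stopover days, merged into maximal runs.
    """
    start, end = span
    dates = pd.date_range(start, end, freq="D").date
    free = []
    for d in dates:
        w0, w1 = night_window_fn(d)
        w0, w1 = pd.Timestamp(w0), pd.Timestamp(w1)
        has_bout = any(b.start < w1 and b.end > w0 for b in bouts)
        free.append(not has_bout)

    stopovers: list[Stopover] = []
    i = 0
    while i < len(dates):
        if free[i]:
            j = i
            while j + 1 < len(dates) and free[j + 1]:
                j += 1
            stopovers.append(Stopover(dates[i], dates[j]))
            i = j + 1
        else:
            i += 1
    return stopovers


def derive_binary_variables(labels: pd.DataFrame, bouts: list[FlightBout]) -> pd.DataFrame:
    """Add ``migrating`` (in a flight bout) and ``foraging`` binary columns.

    Foraging = low or high activity outside any bout, following the reading
    that both non-inactive levels outside flight reflect feeding behaviour;
    the two flags are mutually exclusive by construction.
    """
    out = labels.copy()
    t = pd.to_datetime(out["timestamp"]).to_numpy()
    migrating = np.zeros(len(out), dtype=bool)
    for b in bouts:
        migrating |= (t >= np.datetime64(b.start)) & (t < np.datetime64(b.end))
    state = out["state"].to_numpy()
    if np.any(migrating & (state != "high")):
        warnings.warn("bout overlaps non-high intervals; check gap_tolerance use")
    out["migrating"] = migrating
    out["foraging"] = np.isin(state, ("low", "high")) & ~migrating
    return out
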