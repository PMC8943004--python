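"""Barometric altitude from the International Standard Atmosphere (ISO 2533).

Pressure recorded by an archival tag is converted to altitude above sea level
with the troposphere relation

    H = -(T0 / L) * (1 - (P / P0) ** (1 / 5.2561))

under the standard assumptions P0 = 1013.25 hPa, T0 = 288.15 K and
L = -0.0065 deg/m.  No correction from the tag's temperature sensor is
applied: the quantity of interest is relative altitude change, which the
standard atmosphere serves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "IsaParameters",
    "pressure_to_altitude",
    "altitude_to_pressure",
    "daily_altitude_change",
]


@dataclass(frozen=True)
class IsaParameters:
    p0_hpa: float = 1013.25
    t0_k: float = 288.15
    lapse_rate_deg_per_m: float = -0.0065
    exponent_denominator: float = 5.2561

    def __post_init__(self):
        if self.p0_hpa <= 0 or self.t0_k <= 0:
            raise ValueError("sea-level pressure and temperature must be positive")
        if self.lapse_rate_deg_per_m >= 0:
            raise ValueError("tropospheric lapse rate must be negative")

    @property
    def max_altitude_m(self) -> float:
        """Altitude at which the ISA troposphere pressure reaches zero."""
        return -self.t0_k / self.lapse_rate_deg_per_m


_DEFAULT = IsaParameters()


def pressure_to_altitude(p_hpa, params: IsaParameters = _DEFAULT):
    """Altitude above sea level (m) from pressure (hPa). Vectorised.

    Strictly decreasing in pressure; raises for non-positive pressures.
    """
    p = np.asarray(p_hpa, dtype=float)
    if np.any(p <= 0):
        raise ValueError("pressure must be positive")
    h = -(params.t0_k / params.lapse_rate_deg_per_m) * (
        1.0 - (p / params.p0_hpa) ** (1.0 / params.exponent_denominator)
    )
    return h if h.ndim else float(h)


def altitude_to_pressure(h_m, params: IsaParameters = _DEFAULT):
    """Exact analytic inverse of :func:`pressure_to_altitude`."""
    h = np.asarray(h_m, dtype=float)
    if np.any(h >= params.max_altitude_m):
        raise ValueError(
            f"altitude beyond ISA troposphere validity (< {params.max_altitude_m:.0f} m)"
        )
    p = params.p0_hpa * (
        1.0 + h * params.lapse_rate_deg_per_m / params.t0_k
    ) ** params.exponent_denominator
    return p if p.ndim else float(p)


def daily_altitude_change(timestamps, altitudes_m, *, noon_to_noon: bool = True) -> pd.Series:
    """Per-day max - min altitude (m), the daily vertical range of the bird.

    A "day" is the noon-to-noon UTC window containing the night, so the range
    of a nocturnal flight is attributed to the date the night started on
    (``noon_to_noon=True``); calendar UTC days otherwise.  Days with fewer
    than 2 samples yield NaN.
    """
    t = pd.DatetimeIndex(pd.to_datetime(timestamps))
    if t.tz is not None:
        t = t.tz_convert("UTC").tz_localize(None)
    alt = pd.Series(np.asarray(altitudes_m, dtype=float), index=t)
    key = (t - pd.Timedelta(hours=12)).date if noon_to_noon else t.date
    grouped = alt.groupby(key)
    out = grouped.max() - grouped.min()
    out[grouped.count() < 2] = np.nan
    out.index = pd.to_datetime(out.index)
    out.index.name = "date"
    out.name = "daily_altitude_change_m"
    return out
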