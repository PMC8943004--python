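"""Biome assignment for tracking positions and barrier/hospitable mapping.

GPS fixes are assigned by point sampling the categorical biome raster; the
far less precise light-level position estimates are assigned the *majority*
biome within their 97.5% credible-interval box (area-weighted by cosine of
latitude).  Biomes are then dichotomised into ecological barriers — Desert
and Xeric Shrubland, Mediterranean Forest/Woodland/Scrub, and (Sub)Tropical
Moist Broadleaf Forest (a soft barrier for an aerial insectivore) — versus
hospitable semi-open biomes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rasters import Raster

__all__ = [
    "BIOME_NAMES",
    "DEFAULT_CATEGORY_MAP",
    "ZonalResult",
    "sample_point",
    "zonal_majority",
    "categorize",
    "exclude_singleton_biomes",
]

# WWF-style terrestrial biome codes used throughout the package
BIOME_NAMES = {
    1: "Tropical Moist Broadleaf Forest",
    2: "Tropical Dry Broadleaf Forest",
    3: "Tropical Coniferous Forest",
    4: "Temperate Broadleaf and Mixed Forests",
    5: "Temperate Conifer Forest",
    6: "Boreal Forest",
    7: "Tropical Grassland, Savannah and Shrub",
    8: "Temperate Grassland, Savannah and Shrub",
    9: "Flooded Grassland and Savannah",
    10: "Montane Grassland and Savannah",
    11: "Tundra",
    12: "Mediterranean Forest, Woodland and Scrub",
    13: "Desert and Xeric Shrubland",
    14: "Mangrove",
}

#: barrier = deserts, Mediterranean scrub and tropical moist forest; the rest
#: are semi-open, presumed hospitable.
DEFAULT_CATEGORY_MAP = {
    code: ("barrier" if code in (1, 12, 13) else "hospitable") for code in BIOME_NAMES
}


@dataclass(frozen=True)
class ZonalResult:
    majority_code: int
    majority_fraction: float
    fractions: dict[int, float]
    tie: bool = False


def sample_point(raster: Raster, lon: float, lat: float):
    """Biome code at a point (nearest cell, half-open edges); None if missing."""
    v = raster.sample(lon, lat)
    return None if not np.isfinite(v) else int(v)


def zonal_majority(
    raster: Raster,
    ci_box: tuple[float, float, float, float],
    area_weighted: bool = True,
) -> ZonalResult | None:
    """Most abundant biome inside a (lon_min, lon_max, lat_min, lat_max) box.

    Counts cells whose centres fall in the box; each cell's weight is its
    spherical area (proportional to cos latitude of the cell centre) when
    ``area_weighted``, else 1.  Ties go to the lower code with a tie flag.
    Returns None when the box contains no valid cell centre.
    """
    lon_min, lon_max, lat_min, lat_max = ci_box
    lons, lats = raster.cell_centers()
    ci = np.where((lons >= lon_min) & (lons <= lon_max))[0]
    ri = np.where((lats >= lat_min) & (lats <= lat_max))[0]
    if ci.size == 0 or ri.size == 0:
        return None
    sub = raster.values[np.ix_(ri, ci)].astype(float)
    w = np.cos(np.deg2rad(lats[ri]))[:, None] if area_weighted else np.ones((ri.size, 1))
    w = np.broadcast_to(w, sub.shape)
    valid = sub != raster.nodata
    if not valid.any():
        return None
    codes = sub[valid].astype(int)
    weights = w[valid]
    total = weights.sum()
    fractions: dict[int, float] = {}
    for code in np.unique(codes):
        fractions[int(code)] = float(weights[codes == code].sum() / total)
    best = max(fractions.values())
    winners = sorted(c for c, fr in fractions.items() if np.isclose(fr, best, atol=1e-12))
    return ZonalResult(
        majority_code=winners[0],
        majority_fraction=fractions[winners[0]],
        fractions=fractions,
        tie=len(winners) > 1,
    )


def categorize(code: int, category_map: dict[int, str] | None = None) -> str:
    """Map a biome code to barrier / hospitable / excluded."""
    cmap = DEFAULT_CATEGORY_MAP if category_map is None else category_map
    if code not in cmap:
        raise KeyError(f"biome code {code} missing from category map")
    return cmap[code]


def exclude_singleton_biomes(
    records: pd.DataFrame,
    code_column: str = "biome_code",
    group_columns: tuple[str, ...] = (),
    min_count: int = 2,
) -> pd.DataFrame:
    """Drop records of biomes observed fewer than ``min_count`` times.

    A biome visited only once within a grouping (e.g. a flyway) carries no
    contrast information and is removed before modelling.
    """
    if not len(records):
        return records
    if group_columns:
        counts = records.groupby(list(group_columns))[code_column].transform(
            lambda s: s.map(s.value_counts())
        )
    else:
        counts = records[code_column].map(records[code_column].value_counts())
    return records[counts >= min_count].reset_index(drop=True)
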