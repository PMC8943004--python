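"""ESRI ASCII grid rasters: categorical biome maps, terrain elevation, land/sea.

A minimal regular-grid container with the half-open cell convention
[west, east) x [south, north): a point exactly on a cell edge belongs to the
cell to its east/north, so edge lookups are deterministic.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Raster", "read_ascii_grid", "write_ascii_grid"]

_HEADER_KEYS = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}


@dataclass
class Raster:
    """Regular lon/lat grid; ``values[0, :]`` is the northernmost row."""

    values: np.ndarray
    xllcorner: float
    yllcorner: float
    cellsize: float
    nodata: float = -9999.0

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(west, east, south, north) of the grid in degrees."""
        return (
            self.xllcorner,
            self.xllcorner + self.ncols * self.cellsize,
            self.yllcorner,
            self.yllcorner + self.nrows * self.cellsize,
        )

    def cell_index(self, lon, lat):
        """(row, col) of the cell containing each point; -1 where outside.

        Half-open convention: a point on an interior edge falls in the
        east/north cell; points on the outer east/north boundary are outside.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.xllcorner) / self.cellsize).astype(int)
        row_from_s = np.floor((lat - self.yllcorner) / self.cellsize).astype(int)
        inside = (col >= 0) & (col < self.ncols) & (row_from_s >= 0) & (row_from_s < self.nrows)
        row = self.nrows - 1 - row_from_s
        return np.where(inside, row, -1), np.where(inside, col, -1)

    def sample(self, lon, lat):
        """Nearest-cell value at each point; NaN outside the extent or NODATA."""
        row, col = self.cell_index(lon, lat)
        scalar = np.ndim(row) == 0
        row, col = np.atleast_1d(row), np.atleast_1d(col)
        vals = np.full(row.shape, np.nan)
        ok = row >= 0
        v = self.values[row[ok], col[ok]].astype(float)
        v[v == self.nodata] = np.nan
        vals[ok] = v
        return float(vals[0]) if scalar else vals

    def cell_centers(self):
        """(lons, lats) of column centres / row centres (row 0 = north)."""
        lons = self.xllcorner + (np.arange(self.ncols) + 0.5) * self.cellsize
        lats = self.yllcorner + (self.nrows - np.arange(self.nrows) - 0.5) * self.cellsize
        return lons, lats


def read_ascii_grid(path) -> Raster:
    """Read an ESRI ASCII grid (.asc); header keys in any standard order."""
    text = Path(path).read_text()
    return _parse_ascii(text)


def _parse_ascii(text: str) -> Raster:
    lines = text.splitlines()
    header: dict[str, float] = {}
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for req in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if req not in header:
            raise ValueError(f"missing ESRI ASCII header key: {req}")
    values = np.loadtxt(io.StringIO("\n".join(lines[i:])))
    values = np.atleast_2d(values)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(
            f"grid body {values.shape} does not match header "
            f"({int(header['nrows'])}, {int(header['ncols'])})"
        )
    return Raster(
        values=values,
        xllcorner=header["xllcorner"],
        yllcorner=header["yllcorner"],
        cellsize=header["cellsize"],
        nodata=header.get("nodata_value", -9999.0),
    )


def write_ascii_grid(raster: Raster, path) -> None:
    path = Path(path)
    intlike = np.issubdtype(raster.values.dtype, np.integer)
    fmt = "%d" if intlike else "%.6f"
    with path.open("w") as f:
        f.write(f"ncols {raster.ncols}\n")
        f.write(f"nrows {raster.nrows}\n")
        f.write(f"xllcorner {raster.xllcorner:.10g}\n")
        f.write(f"yllcorner {raster.yllcorner:.10g}\n")
        f.write(f"cellsize {raster.cellsize:.10g}\n")
        nod = int(raster.nodata) if intlike else raster.nodata
        f.write(f"NODATA_value {nod}\n")
        np.savetxt(f, raster.values, fmt=fmt)
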