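"""Regular lat/lon grids and plain-text raster I/O.

A :class:`Raster` is a cell-center-registered regular grid in geographic
coordinates (WGS84 lat/lon degrees). Rasters are read and written as ESRI
ASCII grids (``.asc``) — a plain-text interchange format understood by
GDAL, QGIS and the R ``raster``/``terra`` packages — with square cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Raster", "read_ascii_grid"]

_NODATA = -9999.0


@dataclass
class Raster:
    """A regular geographic grid with one value per cell.

    Attributes
    ----------
    lats : ndarray
        Cell-center latitudes, strictly ascending (row axis of ``values``).
    lons : ndarray
        Cell-center longitudes, strictly ascending (column axis).
    values : ndarray, shape (len(lats), len(lons))
        Cell values. Continuous (snow fraction) or integer class codes.
    """

    lats: np.ndarray
    lons: np.ndarray
    values: np.ndarray
    nodata: float = _NODATA

    def __post_init__(self) -> None:
        self.lats = np.asarray(self.lats, dtype=float)
        self.lons = np.asarray(self.lons, dtype=float)
        self.values = np.asarray(self.values)
        if self.values.shape != (self.lats.size, self.lons.size):
            raise ValueError(
                f"values shape {self.values.shape} does not match grid "
                f"({self.lats.size}, {self.lons.size})"
            )
        for name, ax in (("lats", self.lats), ("lons", self.lons)):
            if ax.size > 1 and not np.all(np.diff(ax) > 0):
                raise ValueError(f"{name} must be strictly ascending")

    @property
    def cellsize(self) -> float:
        steps = np.concatenate([np.diff(self.lats), np.diff(self.lons)])
        if steps.size == 0:
            raise ValueError("cell size undefined for a 1x1 grid")
        if not np.allclose(steps, steps[0]):
            raise ValueError("grid is not uniform; cannot define a single cell size")
        return float(steps[0])

    @classmethod
    def from_bounds(
        cls,
        lat_min: float,
        lat_max: float,
        lon_min: float,
        lon_max: float,
        cellsize: float,
        values: np.ndarray | None = None,
    ) -> "Raster":
        """Build a grid of square cells covering the given bounds.

        ``lat_min``/``lon_min`` are the lower-left *corner*; cell centers sit
        half a cell in from the edges.
        """
        nlat = int(round((lat_max - lat_min) / cellsize))
        nlon = int(round((lon_max - lon_min) / cellsize))
        lats = lat_min + cellsize * (np.arange(nlat) + 0.5)
        lons = lon_min + cellsize * (np.arange(nlon) + 0.5)
        if values is None:
            values = np.zeros((nlat, nlon))
        return cls(lats, lons, values)

    # -- lookup ---------------------------------------------------------

    def cell_index(self, lat, lon):
        """Indices of the cell containing each point.

        A point exactly on a shared cell edge is assigned to the cell with
        the smaller row index, then the smaller column index. Points outside
        the grid extent get index -1.

        Returns
        -------
        (rows, cols) : ndarray of int
        """
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        cs = self.cellsize
        rows = self._axis_index(lat, self.lats[0] - cs / 2.0, cs, self.lats.size)
        cols = self._axis_index(lon, self.lons[0] - cs / 2.0, cs, self.lons.size)
        bad = (rows < 0) | (cols < 0)
        rows[bad] = -1
        cols[bad] = -1
        return rows, cols

    @staticmethod
    def _axis_index(x, edge0, cellsize, n):
        u = (x - edge0) / cellsize
        idx = np.floor(u).astype(int)
        # exact-edge tie -> lower-index cell
        on_edge = (u == idx) & (idx > 0)
        idx[on_edge] -= 1
        idx[(u < 0) | (u > n)] = -1
        idx[idx == n] = -1  # u in (n-?..]; only u==n reached here via edge rule
        return idx

    def value_at(self, lat, lon):
        """Cell value at each point; NaN outside the extent."""
        rows, cols = self.cell_index(lat, lon)
        out = np.full(rows.shape, np.nan, dtype=float)
        ok = rows >= 0
        out[ok] = self.values[rows[ok], cols[ok]].astype(float)
        if np.isscalar(lat) or (np.asarray(lat).ndim == 0):
            return float(out[0])
        return out

    # -- I/O ------------------------------------------------------------

    def write_ascii(self, path: str | Path, fmt: str = "%.4f") -> None:
        """Write as an ESRI ASCII grid (rows north to south)."""
        cs = self.cellsize
        header = (
            f"ncols {self.lons.size}\n"
            f"nrows {self.lats.size}\n"
            f"xllcorner {self.lons[0] - cs / 2.0:.10g}\n"
            f"yllcorner {self.lats[0] - cs / 2.0:.10g}\n"
            f"cellsize {cs:.10g}\n"
            f"NODATA_value {self.nodata:.10g}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, self.values[::-1], fmt=fmt)


def read_ascii_grid(path: str | Path) -> Raster:
    """Read an ESRI ASCII grid written by :meth:`Raster.write_ascii`."""
    with open(path) as fh:
        header = {}
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            parts = fh.readline().split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        values = np.loadtxt(fh)
    nrows = int(header["nrows"])
    ncols = int(header["ncols"])
    values = np.atleast_2d(values)[::-1]
    if values.shape != (nrows, ncols):
        raise ValueError(f"grid body {values.shape} does not match header ({nrows}, {ncols})")
    cs = header["cellsize"]
    lats = header["yllcorner"] + cs * (np.arange(nrows) + 0.5)
    lons = header["xllcorner"] + cs * (np.arange(ncols) + 0.5)
    return Raster(lats, lons, values, nodata=header.get("nodata_value", _NODATA))
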