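"""Analysis lattice, rasters, and coordinate handling.

The pipeline works on a regular square grid in a projected, meter-based
coordinate system (the study default is a 0.25 x 0.25 mile cell, i.e.
402.336 m).  Cells follow the half-open convention: cell (i, j) covers
``[x0 + j*s, x0 + (j+1)*s) x [y0 + i*s, y0 + (i+1)*s)`` with row 0 at the
southern edge, so every point of the extent belongs to exactly one cell.

Occurrence records arrive as WGS84 lon/lat; :class:`LocalEquirectangular`
maps them into grid coordinates.  Rasters are plain 2-D float arrays with
NaN marking missing cells; they round-trip through the text-based ESRI
ASCII grid format (with a small JSON sidecar for the CRS) and can also be
exported as GeoTIFF.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "MILE_QUARTER_M",
    "LocalEquirectangular",
    "GridSpec",
    "Raster",
    "read_ascii_grid",
    "write_ascii_grid",
    "write_geotiff",
]

#: 0.25 mile in meters — the study's cell size.
MILE_QUARTER_M = 402.336

_EARTH_RADIUS_M = 6_371_008.8  # mean Earth radius


@dataclass(frozen=True)
class LocalEquirectangular:
    """Local equirectangular projection centered on (lat0, lon0).

    An affine map between WGS84 degrees and local meters with the
    standard parallel at ``lat0``::

        x = R * cos(lat0) * (lon - lon0) * pi/180
        y = R * (lat - lat0) * pi/180

    Exact round trip; adequate distance fidelity for city-to-region
    extents (distortion grows with |lat - lat0|).
    """

    lat0: float
    lon0: float

    @property
    def crs_id(self) -> str:
        return f"local-equirect({self.lat0:.6f},{self.lon0:.6f})"

    def forward(self, lon, lat):
        """WGS84 degrees -> local meters (x, y)."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        kx = _EARTH_RADIUS_M * math.cos(math.radians(self.lat0)) * math.pi / 180.0
        ky = _EARTH_RADIUS_M * math.pi / 180.0
        return (lon - self.lon0) * kx, (lat - self.lat0) * ky

    def inverse(self, x, y):
        """Local meters -> WGS84 degrees (lon, lat)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        kx = _EARTH_RADIUS_M * math.cos(math.radians(self.lat0)) * math.pi / 180.0
        ky = _EARTH_RADIUS_M * math.pi / 180.0
        return x / kx + self.lon0, y / ky + self.lat0


@dataclass(frozen=True)
class GridSpec:
    """A regular square analysis grid in a projected CRS.

    Parameters
    ----------
    cell_size
        Cell edge length in projected units (meters); default 0.25 mile.
    origin
        (x0, y0) of the lower-left (south-west) grid corner.
    n_rows, n_cols
        Grid shape; row 0 is the southernmost row.
    crs
        Projection mapping WGS84 lon/lat to grid coordinates.  ``None``
        means coordinates are already in grid units.
    """

    n_rows: int
    n_cols: int
    cell_size: float = MILE_QUARTER_M
    origin: tuple[float, float] = (0.0, 0.0)
    crs: LocalEquirectangular | None = None

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def crs_id(self) -> str:
        return self.crs.crs_id if self.crs is not None else "grid-units"

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) in projected units."""
        x0, y0 = self.origin
        return (
            x0,
            y0,
            x0 + self.n_cols * self.cell_size,
            y0 + self.n_rows * self.cell_size,
        )

    def cell_index(self, x, y):
        """Map projected coordinates to (row, col); -1 outside the extent.

        Lower/left edges are inclusive, upper/right exclusive (half-open),
        so a point on an interior shared edge belongs to the cell
        above/right of it.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.origin[0]) / self.cell_size).astype(np.int64)
        row = np.floor((y - self.origin[1]) / self.cell_size).astype(np.int64)
        inside = (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)
        row = np.where(inside, row, -1)
        col = np.where(inside, col, -1)
        return row, col

    def cell_id(self, row, col):
        """Flatten (row, col) to a scalar id; -1 propagates."""
        row = np.asarray(row)
        col = np.asarray(col)
        cid = row * self.n_cols + col
        return np.where((row < 0) | (col < 0), -1, cid)

    def cell_rowcol(self, cell_id):
        cell_id = np.asarray(cell_id)
        return cell_id // self.n_cols, cell_id % self.n_cols

    def cell_centers(self):
        """(x, y) center coordinate arrays, each shaped (n_rows, n_cols)."""
        x0, y0 = self.origin
        xs = x0 + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = y0 + (np.arange(self.n_rows) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def same_frame(self, other: "GridSpec") -> bool:
        """True when both grids live in the same projected frame."""
        return self.crs_id == other.crs_id


@dataclass
class Raster:
    """A single-band raster on a :class:`GridSpec`; NaN marks missing."""

    grid: GridSpec
    values: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"raster shape {self.values.shape} != grid shape {self.grid.shape}"
            )

    @property
    def flat(self) -> np.ndarray:
        """Values flattened in cell_id order (row-major, row 0 = south)."""
        return self.values.ravel()

    def copy(self, name: str | None = None) -> "Raster":
        return Raster(self.grid, self.values.copy(), name if name is not None else self.name)

    def sample_cells(self, cell_ids) -> np.ndarray:
        """Values at the given cell ids (NaN for id -1)."""
        cell_ids = np.asarray(cell_ids)
        out = np.full(cell_ids.shape, np.nan)
        ok = cell_ids >= 0
        out[ok] = self.flat[cell_ids[ok]]
        return out


_NODATA = -9999.0


def write_ascii_grid(path, raster: Raster) -> None:
    """Write an ESRI ASCII grid (.asc) plus a JSON CRS sidecar (.asc.aux.json)."""
    path = Path(path)
    g = raster.grid
    vals = np.where(np.isfinite(raster.values), raster.values, _NODATA)
    with open(path, "w") as fh:
        fh.write(f"ncols {g.n_cols}\n")
        fh.write(f"nrows {g.n_rows}\n")
        fh.write(f"xllcorner {g.origin[0]!r}\n")
        fh.write(f"yllcorner {g.origin[1]!r}\n")
        fh.write(f"cellsize {g.cell_size!r}\n")
        fh.write(f"NODATA_value {_NODATA!r}\n")
        # ASCII grids are written north-up; our row 0 is the south row.
        np.savetxt(fh, vals[::-1], fmt="%.10g")
    aux = {"name": raster.name}
    if g.crs is not None:
        aux["crs"] = {"type": "local-equirect", "lat0": g.crs.lat0, "lon0": g.crs.lon0}
    with open(str(path) + ".aux.json", "w") as fh:
        json.dump(aux, fh)


def read_ascii_grid(path) -> Raster:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        vals = np.loadtxt(fh, ndmin=2)
    nodata = header.get("nodata_value", _NODATA)
    vals = np.where(vals == nodata, np.nan, vals)[::-1]
    crs = None
    name = ""
    aux_path = Path(str(path) + ".aux.json")
    if aux_path.exists():
        aux = json.loads(aux_path.read_text())
        name = aux.get("name", "")
        if "crs" in aux:
            crs = LocalEquirectangular(aux["crs"]["lat0"], aux["crs"]["lon0"])
    grid = GridSpec(
        n_rows=int(header["nrows"]),
        n_cols=int(header["ncols"]),
        cell_size=header["cellsize"],
        origin=(header["xllcorner"], header["yllcorner"]),
        crs=crs,
    )
    return Raster(grid, vals, name=name)


def write_geotiff(path, raster: Raster) -> None:
    """Write the raster as a GeoTIFF (float32, NaN nodata).

    Georeferencing is carried by the ModelPixelScale / ModelTiepoint tags;
    the projected frame is the grid's local CRS (not an EPSG code), so the
    file is a georeferenced TIFF for viewing, not a datum-exact product.
    """
    import tifffile

    g = raster.grid
    xmin, _, _, ymax = g.extent
    # north-up image: flip rows
    data = raster.values[::-1].astype(np.float32)
    extratags = [
        (33550, "d", 3, (g.cell_size, g.cell_size, 0.0)),  # ModelPixelScaleTag
        (33922, "d", 6, (0.0, 0.0, 0.0, xmin, ymax, 0.0)),  # ModelTiepointTag
        (42113, "s", 0, "nan"),  # GDAL_NODATA
    ]
    tifffile.imwrite(path, data, extratags=extratags)
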