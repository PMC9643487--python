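"""Raster data model and geometric primitives shared by the landscape modules.

The package works on projected planar grids with square cells, lower-left
origin, and row 0 as the southernmost row (cell centres at
``origin + (index + 0.5) * cell_size``).  Two plain-text/standard formats are
supported: ESRI ASCII grid and single-band float32 GeoTIFF.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "TerrainGrid",
    "PointSite",
    "GridFormatError",
    "read_grid",
    "write_grid",
    "slope_degrees",
    "distance_to_mask",
    "equirectangular_project",
    "read_sites",
    "write_sites",
]

DEFAULT_NODATA = -9999.0

#: GeoTIFF tag codes used for georeferencing a single-band raster.
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


class GridFormatError(ValueError):
    """Raised for unreadable, malformed, or unsupported raster files."""


@dataclass
class TerrainGrid:
    """A georeferenced rectangular raster with uniform square cells.

    Parameters
    ----------
    values : ndarray, shape (nrows, ncols)
        Cell values; row 0 is the southernmost row.  Units depend on the
        variable (elevation m, uplift m/yr, precipitation m/yr, discharge
        m3/s, resistance dimensionless in [0, 1]).
    cell_size : float
        Cell edge length in metres.
    origin : tuple of float
        (x, y) of the lower-left corner of the lower-left cell, in
        projected metres.
    nodata : float
        Sentinel value marking missing cells.
    variable : str
        Free-text variable name ("elevation", "resistance", ...).
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float = DEFAULT_NODATA
    variable: str = "value"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("grid values must be a 2-D array")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")
        self.origin = (float(self.origin[0]), float(self.origin[1]))
        if self.variable == "resistance":
            v = self.values[self.mask_valid]
            if v.size and (v.min() < 0 or v.max() > 1):
                raise ValueError("resistance values must lie in [0, 1]")

    # -- basic geometry -------------------------------------------------
    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def mask_valid(self) -> np.ndarray:
        """Boolean array, True where the cell holds data."""
        with np.errstate(invalid="ignore"):
            return ~(np.isnan(self.values) | (self.values == self.nodata))

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid bounding box."""
        x0, y0 = self.origin
        return (x0, y0, x0 + self.ncols * self.cell_size, y0 + self.nrows * self.cell_size)

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x0, y0 = self.origin
        return (x0 + (col + 0.5) * self.cell_size, y0 + (row + 0.5) * self.cell_size)

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """Row/col of the cell containing (x, y); raises if outside."""
        x0, y0 = self.origin
        col = int(math.floor((x - x0) / self.cell_size))
        row = int(math.floor((y - y0) / self.cell_size))
        if not (0 <= row < self.nrows and 0 <= col < self.ncols):
            raise ValueError(f"point ({x}, {y}) falls outside the grid bounds")
        return row, col

    def contains(self, x: float, y: float) -> bool:
        xmin, ymin, xmax, ymax = self.bounds
        return xmin <= x < xmax and ymin <= y < ymax

    def congruent_with(self, other: "TerrainGrid") -> bool:
        return (
            self.values.shape == other.values.shape
            and math.isclose(self.cell_size, other.cell_size)
            and math.isclose(self.origin[0], other.origin[0])
            and math.isclose(self.origin[1], other.origin[1])
        )

    def like(self, values: np.ndarray, variable: str | None = None) -> "TerrainGrid":
        """New grid sharing this grid's geometry."""
        return replace(
            self,
            values=np.asarray(values, dtype=float),
            variable=variable if variable is not None else self.variable,
        )

    def plot(self, ax=None, **imshow_kw):
        """Quick-look map (matplotlib); rows displayed south-up."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        xmin, ymin, xmax, ymax = self.bounds
        shown = np.where(self.mask_valid, self.values, np.nan)
        im = ax.imshow(
            shown, origin="lower", extent=(xmin, xmax, ymin, ymax), **imshow_kw
        )
        ax.set_xlabel("x (m)")
        ax.set_ylabel("y (m)")
        ax.set_title(self.variable)
        return im


@dataclass(frozen=True)
class PointSite:
    """A named point (entry point, target site) in projected metres."""

    x: float
    y: float
    label: str = ""


def _require_congruent(a: TerrainGrid, b: TerrainGrid) -> None:
    if not a.congruent_with(b):
        raise ValueError("grids are not congruent (shape/cell_size/origin differ)")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_grid(path: str | Path, variable: str = "value") -> TerrainGrid:
    """Read a single-band raster (ESRI ASCII grid or GeoTIFF).

    The format is chosen by file suffix: ``.asc``/``.txt`` parse as ESRI
    ASCII, ``.tif``/``.tiff`` as GeoTIFF; anything else is tried as ASCII.
    """
    path = Path(path)
    if not path.exists():
        raise GridFormatError(f"no such raster file: {path}")
    if path.suffix.lower() in (".tif", ".tiff"):
        return _read_geotiff(path, variable)
    return _read_esri_ascii(path, variable)


def write_grid(grid: TerrainGrid, path: str | Path) -> None:
    """Write a grid, format chosen by suffix (see :func:`read_grid`)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        _write_geotiff(grid, path)
    else:
        _write_esri_ascii(grid, path)


def _read_esri_ascii(path: Path, variable: str) -> TerrainGrid:
    header: dict[str, float] = {}
    data_tokens: list[str] = []
    with open(path) as fh:
        for line in fh:
            tokens = line.split()
            if not tokens:
                continue
            key = tokens[0].lower()
            if not data_tokens and key in (
                "ncols", "nrows", "xllcorner", "yllcorner",
                "cellsize", "nodata_value",
            ):
                if len(tokens) != 2:
                    raise GridFormatError(f"malformed header line in {path}: {line!r}")
                header[key] = float(tokens[1])
            elif not data_tokens and key in ("dx", "dy", "xllcenter", "yllcenter"):
                raise GridFormatError(
                    f"unsupported ESRI ASCII keyword {key!r} (non-square cells or "
                    "centre-registered grids are not supported)"
                )
            else:
                data_tokens.extend(tokens)
    for required in ("ncols", "nrows", "cellsize"):
        if required not in header:
            raise GridFormatError(f"missing {required} in ESRI ASCII header of {path}")
    ncols = int(header["ncols"])
    nrows = int(header["nrows"])
    if len(data_tokens) != nrows * ncols:
        raise GridFormatError(
            f"{path}: expected {nrows * ncols} values, found {len(data_tokens)}"
        )
    try:
        flat = np.array([float(t) for t in data_tokens])
    except ValueError as exc:
        raise GridFormatError(f"{path}: non-numeric cell value ({exc})") from exc
    values = flat.reshape(nrows, ncols)[::-1]  # file stores the top row first
    return TerrainGrid(
        values=values,
        cell_size=header["cellsize"],
        origin=(header.get("xllcorner", 0.0), header.get("yllcorner", 0.0)),
        nodata=header.get("nodata_value", DEFAULT_NODATA),
        variable=variable,
    )


def _write_esri_ascii(grid: TerrainGrid, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {grid.origin[0]:.17g}\n")
        fh.write(f"yllcorner {grid.origin[1]:.17g}\n")
        fh.write(f"cellsize {grid.cell_size:.17g}\n")
        fh.write(f"NODATA_value {grid.nodata:.17g}\n")
        out = np.where(grid.mask_valid, grid.values, grid.nodata)
        for row in out[::-1]:
            fh.write(" ".join(f"{v:.17g}" for v in row))
            fh.write("\n")


def _read_geotiff(path: Path, variable: str) -> TerrainGrid:
    import tifffile

    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        values = page.asarray()
        if values.ndim != 2:
            raise GridFormatError(f"{path}: not a single-band raster")
        tags = page.tags
        if _TAG_MODEL_PIXEL_SCALE not in tags or _TAG_MODEL_TIEPOINT not in tags:
            raise GridFormatError(f"{path}: missing GeoTIFF georeferencing tags")
        sx, sy = tags[_TAG_MODEL_PIXEL_SCALE].value[:2]
        if not math.isclose(sx, sy, rel_tol=1e-9):
            raise GridFormatError(f"{path}: non-square cells ({sx} x {sy}) unsupported")
        tiepoint = tags[_TAG_MODEL_TIEPOINT].value
        x_top_left, y_top_left = tiepoint[3], tiepoint[4]
        nodata = DEFAULT_NODATA
        if _TAG_GDAL_NODATA in tags:
            nodata = float(tags[_TAG_GDAL_NODATA].value)
    nrows = values.shape[0]
    origin = (float(x_top_left), float(y_top_left) - nrows * float(sx))
    return TerrainGrid(
        values=np.asarray(values, dtype=float)[::-1],
        cell_size=float(sx),
        origin=origin,
        nodata=nodata,
        variable=variable,
    )


def _write_geotiff(grid: TerrainGrid, path: Path) -> None:
    import tifffile

    cs = float(grid.cell_size)
    x0, y0 = grid.origin
    y_top = y0 + grid.nrows * cs
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (cs, cs, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, x0, y_top, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, str(grid.nodata)),
    ]
    out = np.where(grid.mask_valid, grid.values, grid.nodata)
    tifffile.imwrite(str(path), out[::-1].astype(np.float32), extratags=extratags)


# ---------------------------------------------------------------------------
# Geometric operations
# ---------------------------------------------------------------------------

def slope_degrees(elevation: TerrainGrid) -> TerrainGrid:
    """Local slope in degrees from Horn's 8-neighbour finite differences.

    Edge cells are handled by linear extrapolation of the surface, which
    reduces the stencil to a one-sided difference there (exact for planes).
    """
    z = elevation.values
    if z.shape[0] < 2 or z.shape[1] < 2:
        raise ValueError("slope requires a grid of at least 2x2 cells")
    zp = np.pad(z, 1, mode="edge")
    # linear extrapolation along each edge keeps planes exact
    zp[0, :] = 2 * zp[1, :] - zp[2, :]
    zp[-1, :] = 2 * zp[-2, :] - zp[-3, :]
    zp[:, 0] = 2 * zp[:, 1] - zp[:, 2]
    zp[:, -1] = 2 * zp[:, -2] - zp[:, -3]
    cs = elevation.cell_size
    # Horn kernel: weights 1-2-1 across the three neighbouring rows/cols
    dzdx = (
        (zp[:-2, 2:] + 2 * zp[1:-1, 2:] + zp[2:, 2:])
        - (zp[:-2, :-2] + 2 * zp[1:-1, :-2] + zp[2:, :-2])
    ) / (8.0 * cs)
    dzdy = (
        (zp[2:, :-2] + 2 * zp[2:, 1:-1] + zp[2:, 2:])
        - (zp[:-2, :-2] + 2 * zp[:-2, 1:-1] + zp[:-2, 2:])
    ) / (8.0 * cs)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    slope = np.where(elevation.mask_valid, slope, elevation.nodata)
    return elevation.like(slope, variable="slope")


def distance_to_mask(mask: TerrainGrid) -> TerrainGrid:
    """Euclidean distance (m) from each cell centre to the nearest True cell."""
    m = mask.values.astype(bool)
    if not m.any():
        raise ValueError("distance_to_mask requires at least one True cell")
    dist = ndimage.distance_transform_edt(~m, sampling=mask.cell_size)
    return mask.like(dist, variable="distance")


_EARTH_RADIUS_M = 6_371_000.0


def equirectangular_project(
    lon: np.ndarray | float, lat: np.ndarray | float, lat_origin: float
) -> tuple[np.ndarray, np.ndarray]:
    """Project geographic degrees to planar metres at a reference latitude.

    A desk-scale helper for placing geographic points on synthetic grids;
    x = R cos(lat0) lon, y = R lat (angles in radians).
    """
    lon = np.radians(np.asarray(lon, dtype=float))
    lat = np.radians(np.asarray(lat, dtype=float))
    k = _EARTH_RADIUS_M * math.cos(math.radians(lat_origin))
    return k * lon, _EARTH_RADIUS_M * lat


# ---------------------------------------------------------------------------
# Point-site tables
# ---------------------------------------------------------------------------

def read_sites(path: str | Path) -> list[PointSite]:
    """Read point sites from a CSV with columns ``label,x,y``."""
    sites = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            sites.append(PointSite(x=float(row["x"]), y=float(row["y"]), label=row["label"]))
    return sites


def write_sites(sites: list[PointSite], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["label", "x", "y"])
        for s in sites:
            writer.writerow([s.label, f"{s.x:.17g}", f"{s.y:.17g}"])
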