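"""Georeferenced grid data model: ESRI ASCII grid I/O, GeoTIFF read, cropping,
and nearest-neighbour resampling.

Conventions
-----------
* Row 0 is the northernmost row; ``origin_x``/``origin_y`` are the west and
  north *edges* of the grid (WGS84 degrees treated as planar — the analysis
  operates at ~1-km cells over a single administrative division, where
  great-circle corrections are negligible).
* Cell ``(r, c)`` spans the half-open box
  ``[origin_x + c*cs, origin_x + (c+1)*cs) x (origin_y - (r+1)*cs, origin_y - r*cs]``
  so a point on a shared edge belongs to exactly one cell; points on the east
  or south outer edge fall outside the grid.
* Nodata is a boolean mask internally; the ``-9999`` sentinel only exists in
  files.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass

import numpy as np
import shapely

__all__ = [
    "RasterGrid",
    "StudyArea",
    "GridFormatError",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_geotiff",
    "read_grid",
    "resample_nearest",
    "crop_to_area",
]

NODATA_SENTINEL = -9999.0


class GridFormatError(ValueError):
    """Raised when a raster file does not parse."""


@dataclass
class RasterGrid:
    """One georeferenced value grid with a nodata mask.

    Parameters
    ----------
    values
        2-D float array, row-major from the north-west corner.
    mask
        Boolean array of the same shape; ``True`` marks nodata cells.
    origin_x, origin_y
        West edge and north edge coordinates (degrees, WGS84).
    cell_size
        Positive cell edge length in degrees.
    crs_label
        Free-text CRS tag, default ``"WGS84"``.
    """

    values: np.ndarray
    mask: np.ndarray
    origin_x: float
    origin_y: float
    cell_size: float
    crs_label: str = "WGS84"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 2 or self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise ValueError("values must be 2-D with at least one row and column")
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape must match values shape")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")

    # -- georeference helpers -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_valid(self) -> int:
        return int((~self.mask).sum())

    def x_centers(self) -> np.ndarray:
        """Cell-centre x coordinates, west to east."""
        return self.origin_x + (np.arange(self.shape[1]) + 0.5) * self.cell_size

    def y_centers(self) -> np.ndarray:
        """Cell-centre y coordinates, north to south."""
        return self.origin_y - (np.arange(self.shape[0]) + 0.5) * self.cell_size

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        xs, ys = np.meshgrid(self.x_centers(), self.y_centers())
        return xs, ys

    def cell_of(self, x, y) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Map point coordinates to (row, col, inside) under the half-open rule.

        ``inside`` is False for points outside the grid extent; their row/col
        entries are clipped and must not be used.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.origin_x) / self.cell_size).astype(int)
        # rows count downward from the north edge; each cell is closed at its
        # north edge and open at its south edge, so row = floor(downward
        # distance): a point on a shared horizontal edge belongs to the cell
        # below, the north outer edge to row 0, the south outer edge to none
        d = (self.origin_y - y) / self.cell_size
        row = np.floor(d).astype(int)
        nr, nc = self.shape
        inside = (col >= 0) & (col < nc) & (row >= 0) & (row < nr)
        return np.clip(row, 0, nr - 1), np.clip(col, 0, nc - 1), inside

    def same_georef(self, other: "RasterGrid", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and math.isclose(self.origin_x, other.origin_x, rel_tol=0, abs_tol=tol)
            and math.isclose(self.origin_y, other.origin_y, rel_tol=0, abs_tol=tol)
            and math.isclose(self.cell_size, other.cell_size, rel_tol=0, abs_tol=tol)
        )

    def valid_values(self) -> np.ndarray:
        """1-D array of unmasked cell values."""
        return self.values[~self.mask]

    def with_values(self, values: np.ndarray, mask: np.ndarray | None = None) -> "RasterGrid":
        """Same georeference, new values (and optionally a new mask)."""
        return RasterGrid(
            values=np.asarray(values, dtype=float),
            mask=self.mask.copy() if mask is None else np.asarray(mask, dtype=bool),
            origin_x=self.origin_x,
            origin_y=self.origin_y,
            cell_size=self.cell_size,
            crs_label=self.crs_label,
        )

    def copy(self) -> "RasterGrid":
        return self.with_values(self.values.copy())

    def __eq__(self, other) -> bool:  # bit-exact comparison, used by round-trip tests
        if not isinstance(other, RasterGrid):
            return NotImplemented
        return (
            self.same_georef(other, tol=0.0)
            and np.array_equal(self.mask, other.mask)
            and np.array_equal(self.values[~self.mask], other.values[~other.mask])
        )


@dataclass
class StudyArea:
    """Study-area polygon in the grid coordinate system (WGS84 lon/lat)."""

    polygon: shapely.Geometry

    def __post_init__(self) -> None:
        if not isinstance(self.polygon, (shapely.Polygon, shapely.MultiPolygon)):
            raise ValueError("StudyArea requires a Polygon or MultiPolygon")
        if self.polygon.is_empty or self.polygon.area <= 0:
            raise ValueError("study-area polygon has zero area")

    @classmethod
    def from_vertices(cls, vertices) -> "StudyArea":
        """Build from a closed ring of (x, y) vertices (first == last)."""
        vertices = list(vertices)
        if len(vertices) < 4 or tuple(vertices[0]) != tuple(vertices[-1]):
            raise ValueError("ring must be closed (first vertex == last) with >= 3 distinct points")
        return cls(shapely.Polygon(vertices))

    @classmethod
    def from_geojson(cls, path) -> "StudyArea":
        """Read a Polygon/MultiPolygon from a GeoJSON file.

        Accepts a bare geometry, a Feature, or a FeatureCollection (first
        polygonal feature is used).
        """
        with open(path) as fh:
            obj = json.load(fh)
        geom = _geojson_geometry(obj)
        if geom is None:
            raise GridFormatError(f"no Polygon/MultiPolygon geometry found in {path}")
        return cls(geom)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return self.polygon.bounds

    def contains_xy(self, x, y) -> np.ndarray:
        """Vectorised point-in-polygon (boundary counts as inside)."""
        return shapely.intersects_xy(self.polygon, np.asarray(x, float), np.asarray(y, float))


def _geojson_geometry(obj):
    t = obj.get("type")
    if t in ("Polygon", "MultiPolygon"):
        return shapely.geometry.shape(obj)
    if t == "Feature":
        return _geojson_geometry(obj["geometry"])
    if t == "FeatureCollection":
        for feat in obj.get("features", []):
            g = _geojson_geometry(feat)
            if g is not None:
                return g
    return None


# -- ESRI ASCII grid I/O ------------------------------------------------------

_ASCII_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def read_ascii_grid(path) -> RasterGrid:
    """Read an ESRI ASCII grid (.asc). Header keys are case-insensitive;
    the lower-left-corner convention is converted to a north-west origin."""
    header: dict[str, float] = {}
    rows: list[np.ndarray] = []
    nodata = NODATA_SENTINEL
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if not parts:
            continue
        key = parts[0].lower()
        if key in _ASCII_HEADER_KEYS or key == "nodata_value":
            if len(parts) != 2:
                raise GridFormatError(f"{path}: malformed header line {i + 1}: {line.strip()!r}")
            try:
                val = float(parts[1])
            except ValueError as exc:
                raise GridFormatError(
                    f"{path}: unparseable header value on line {i + 1}: {line.strip()!r}"
                ) from exc
            if key == "nodata_value":
                nodata = val
            else:
                header[key] = val
        else:
            break
    missing = [k for k in _ASCII_HEADER_KEYS if k not in header]
    if missing:
        raise GridFormatError(f"{path}: missing header keys: {', '.join(missing)}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    for j in range(i, len(lines)):
        parts = lines[j].split()
        if not parts:
            continue
        try:
            row = np.array([float(v) for v in parts])
        except ValueError as exc:
            raise GridFormatError(f"{path}: unparseable data on line {j + 1}") from exc
        if row.size != ncols:
            raise GridFormatError(
                f"{path}: line {j + 1} has {row.size} values, expected ncols={ncols}"
            )
        rows.append(row)
    if len(rows) != nrows:
        raise GridFormatError(f"{path}: found {len(rows)} data rows, expected nrows={nrows}")
    values = np.vstack(rows)
    mask = values == nodata
    values = np.where(mask, np.nan, values)
    cs = header["cellsize"]
    return RasterGrid(
        values=values,
        mask=mask,
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"] + nrows * cs,
        cell_size=cs,
    )


def write_ascii_grid(grid: RasterGrid, path, nodata: float = NODATA_SENTINEL) -> None:
    """Write an ESRI ASCII grid. Values are written with up to 17 significant
    digits so finite values round-trip bit-exactly; if a data value collides
    with the nodata sentinel, a sentinel below the data minimum is used."""
    nrows, ncols = grid.shape
    valid = grid.values[~grid.mask]
    if valid.size and np.any(valid == nodata):
        nodata = float(np.floor(valid.min()) - 1.0)
    out = np.where(grid.mask, nodata, grid.values)
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {grid.origin_x!r}\n")
        fh.write(f"yllcorner {grid.origin_y - nrows * grid.cell_size!r}\n")
        fh.write(f"cellsize {grid.cell_size!r}\n")
        fh.write(f"NODATA_value {nodata:g}\n")
        for r in range(nrows):
            fh.write(" ".join(f"{v:.17g}" for v in out[r]) + "\n")


# -- GeoTIFF read -------------------------------------------------------------

def read_geotiff(path) -> RasterGrid:
    """Read a single-band float GeoTIFF via :mod:`tifffile`.

    Georeference is taken from the ModelPixelScale and ModelTiepoint GeoTIFF
    tags; nodata from the GDAL_NODATA tag when present. Square pixels are
    required (the pipeline resamples everything to one cell size anyway).
    """
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        arr = page.asarray()
        tags = {t.name: t.value for t in page.tags.values()}
    if arr.ndim == 3:
        if arr.shape[2] != 1:
            raise GridFormatError(f"{path}: multi-band GeoTIFF not supported")
        arr = arr[:, :, 0]
    scale = tags.get("ModelPixelScaleTag")
    tiepoint = tags.get("ModelTiepointTag")
    if scale is None or tiepoint is None:
        raise GridFormatError(f"{path}: missing GeoTIFF georeferencing tags")
    sx, sy = float(scale[0]), float(scale[1])
    if not math.isclose(sx, sy, rel_tol=1e-6):
        raise GridFormatError(f"{path}: non-square pixels ({sx} x {sy}) not supported")
    # tiepoint maps raster point (i, j, k) -> model point (x, y, z)
    i, j = float(tiepoint[0]), float(tiepoint[1])
    x, y = float(tiepoint[3]), float(tiepoint[4])
    origin_x = x - i * sx
    origin_y = y + j * sy
    values = np.asarray(arr, dtype=float)
    mask = ~np.isfinite(values)
    nodata_tag = tags.get("GDAL_NODATA")
    if nodata_tag is not None:
        mask |= values == float(nodata_tag)
    values = np.where(mask, np.nan, values)
    return RasterGrid(values=values, mask=mask, origin_x=origin_x, origin_y=origin_y, cell_size=sx)


def read_grid(path, format: str | None = None) -> RasterGrid:
    """Read a raster, dispatching on ``format`` or the file extension.

    ``format`` may be ``"ascii_grid"`` or ``"geotiff"``.
    """
    if format is None:
        s = str(path).lower()
        format = "geotiff" if s.endswith((".tif", ".tiff")) else "ascii_grid"
    if format == "ascii_grid":
        return read_ascii_grid(path)
    if format == "geotiff":
        return read_geotiff(path)
    raise ValueError(f"unknown raster format: {format!r}")


# -- spatial operations -------------------------------------------------------

def resample_nearest(src: RasterGrid, origin_x: float, origin_y: float,
                     cell_size: float, shape: tuple[int, int]) -> RasterGrid:
    """Nearest-neighbour resample onto a target georeference.

    Each target cell takes the value of the source cell whose centre is
    nearest to the target cell centre; exact distance ties break toward the
    smaller row index, then the smaller column index. Target cells whose
    centres fall outside the source extent become nodata; if the extents are
    disjoint the result is all nodata and a warning is issued.
    """
    nrows, ncols = shape
    if nrows < 1 or ncols < 1:
        raise ValueError("target shape must be at least 1x1")
    tx = origin_x + (np.arange(ncols) + 0.5) * cell_size
    ty = origin_y - (np.arange(nrows) + 0.5) * cell_size
    # fractional index of the nearest source centre; ceil(d - 0.5) breaks
    # exact .5 ties toward the smaller index
    fx = (tx - src.origin_x) / src.cell_size - 0.5
    fy = (src.origin_y - ty) / src.cell_size - 0.5
    col = np.ceil(fx - 0.5).astype(int)
    row = np.ceil(fy - 0.5).astype(int)
    snr, snc = src.shape
    in_x = (tx >= src.origin_x) & (tx < src.origin_x + snc * src.cell_size)
    in_y = (ty <= src.origin_y) & (ty > src.origin_y - snr * src.cell_size)
    inside = in_y[:, None] & in_x[None, :]
    if not inside.any():
        warnings.warn("resample_nearest: target extent is disjoint from source; all nodata")
    col = np.clip(col, 0, snc - 1)
    row = np.clip(row, 0, snr - 1)
    values = src.values[row[:, None], col[None, :]]
    mask = src.mask[row[:, None], col[None, :]] | ~inside
    values = np.where(mask, np.nan, values)
    return RasterGrid(values=values, mask=mask, origin_x=origin_x, origin_y=origin_y,
                      cell_size=cell_size, crs_label=src.crs_label)


def crop_to_area(grid: RasterGrid, area: StudyArea) -> RasterGrid:
    """Mask cells whose centre lies strictly outside the study-area polygon.

    The georeference is unchanged (no shrink-wrapping of the extent).
    """
    xs, ys = grid.center_mesh()
    inside = area.contains_xy(xs.ravel(), ys.ravel()).reshape(grid.shape)
    mask = grid.mask | ~inside
    return grid.with_values(np.where(mask, np.nan, grid.values), mask=mask)
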