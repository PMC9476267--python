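"""Digital elevation model handling: I/O, slope/aspect derivation, fix annotation.

The DEM is a regular grid registered to cell centres with (row 0, col 0) at the
north-west corner.  Slope and aspect are derived with Horn's 3x3 finite
differences (the standard GIS rule) with a replicated border so edge cells get
values too.  Fixes are annotated by nearest-cell sampling by default; bilinear
interpolation is available for elevation.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: per-fix annotation columns added by :func:`annotate_fixes`
ANNOTATION_COLUMNS = ("elevation", "slope_deg", "slope_pct", "aspect_deg")


class DemFormatError(ValueError):
    """Raised when a DEM file cannot be parsed or lacks georeferencing."""


@dataclasses.dataclass
class DemGrid:
    """Elevation raster in planar metric coordinates.

    Parameters
    ----------
    xll, yll:
        Coordinates of the *lower-left corner* of the grid (metres).
    cell:
        Cell size in metres (square cells).
    elev:
        ``(n_rows, n_cols)`` elevation matrix in metres; row 0 is the
        northernmost row.
    nodata:
        Sentinel used on disk for missing cells; in memory missing cells are
        NaN.
    """

    xll: float
    yll: float
    cell: float
    elev: np.ndarray
    nodata: float = -9999.0
    # derived grids, filled by compute_slope_aspect()
    slope_deg: np.ndarray | None = None
    slope_pct: np.ndarray | None = None
    aspect_deg: np.ndarray | None = None
    flat: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.elev = np.asarray(self.elev, dtype=float)
        if self.cell <= 0:
            raise DemFormatError(f"cell size must be positive, got {self.cell}")
        if self.elev.ndim != 2 or min(self.elev.shape) < 1:
            raise DemFormatError("elevation matrix must be 2-D and non-empty")

    @property
    def n_rows(self) -> int:
        return self.elev.shape[0]

    @property
    def n_cols(self) -> int:
        return self.elev.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid's outer edges."""
        return (
            self.xll,
            self.yll,
            self.xll + self.n_cols * self.cell,
            self.yll + self.n_rows * self.cell,
        )

    @property
    def nodata_mask(self) -> np.ndarray:
        return ~np.isfinite(self.elev)

    def cell_centre(self, row: int, col: int) -> tuple[float, float]:
        x = self.xll + (col + 0.5) * self.cell
        y = self.yll + (self.n_rows - row - 0.5) * self.cell
        return x, y

    def index_of(self, x, y):
        """Row/col of the cell containing (x, y); arrays accepted.

        Points outside the extent get indices clipped into range; use
        :meth:`contains` to detect them.
        """
        col = np.floor((np.asarray(x) - self.xll) / self.cell).astype(int)
        row = self.n_rows - 1 - np.floor((np.asarray(y) - self.yll) / self.cell).astype(int)
        return np.clip(row, 0, self.n_rows - 1), np.clip(col, 0, self.n_cols - 1)

    def contains(self, x, y):
        xmin, ymin, xmax, ymax = self.extent
        x = np.asarray(x)
        y = np.asarray(y)
        return (x >= xmin) & (x < xmax) & (y >= ymin) & (y < ymax)


# ---------------------------------------------------------------------------
# slope / aspect
# ---------------------------------------------------------------------------

def compute_slope_aspect(dem: DemGrid, flat_tol: float = 1e-12) -> DemGrid:
    """Fill the slope and aspect grids of ``dem`` in place (and return it).

    Horn's method estimates the elevation gradient in a 3x3 window with
    weights (1, 2, 1); the border is replicated so the result covers the whole
    grid.  Slope is reported both in degrees, ``atan(|grad|)``, and as
    rise/run percent, ``100 * |grad|``.  Aspect is the downslope azimuth in
    degrees clockwise from north; cells with |grad| <= ``flat_tol`` are
    flagged flat and get NaN aspect.
    """
    if dem.n_rows < 3 or dem.n_cols < 3:
        raise DemFormatError("slope/aspect need at least a 3x3 grid")
    z = np.pad(dem.elev, 1, mode="edge")
    # window corners: a b c / d e f / g h i, row 0 north
    a = z[:-2, :-2]; b = z[:-2, 1:-1]; c = z[:-2, 2:]
    d = z[1:-1, :-2]; f = z[1:-1, 2:]
    g = z[2:, :-2]; h = z[2:, 1:-1]; i = z[2:, 2:]
    gx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8.0 * dem.cell)  # dz/dx (east+)
    gy = ((a + 2 * b + c) - (g + 2 * h + i)) / (8.0 * dem.cell)  # dz/dy (north+)
    grad = np.hypot(gx, gy)
    dem.slope_deg = np.degrees(np.arctan(grad))
    dem.slope_pct = 100.0 * grad
    dem.flat = grad <= flat_tol
    aspect = np.degrees(np.arctan2(-gx, -gy)) % 360.0  # downslope azimuth
    aspect[dem.flat] = np.nan
    dem.aspect_deg = aspect
    return dem


def slope_percent_to_degrees(pct, convention: str = "tan"):
    """Convert percent slope to degrees.

    ``tan``: the geometric rise/run definition, ``atan(pct/100)``.
    ``linear``: the linear 45-degrees-is-100-percent mapping, ``pct * 45/100``
    (seen in some reporting).  Both are provided because field reports mix
    them; the geometric one is the default everywhere in this package.
    """
    pct = np.asarray(pct, dtype=float)
    if convention == "tan":
        return np.degrees(np.arctan(pct / 100.0))
    if convention == "linear":
        return pct * 45.0 / 100.0
    raise ValueError(f"unknown slope convention {convention!r}")


def slope_degrees_to_percent(deg, convention: str = "tan"):
    deg = np.asarray(deg, dtype=float)
    if convention == "tan":
        return 100.0 * np.tan(np.radians(deg))
    if convention == "linear":
        return deg * 100.0 / 45.0
    raise ValueError(f"unknown slope convention {convention!r}")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_dem(path) -> DemGrid:
    """Read a DEM from an ESRI ASCII grid (.asc) or a GeoTIFF (.tif/.tiff)."""
    p = str(path)
    if p.lower().endswith((".asc", ".grd", ".txt")):
        return read_esri_ascii(p)
    if p.lower().endswith((".tif", ".tiff")):
        return read_geotiff(p)
    raise DemFormatError(f"unsupported DEM format: {p}")


def read_esri_ascii(path) -> DemGrid:
    header: dict[str, float] = {}
    n_header = 0
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner",
                "xllcenter", "yllcenter", "cellsize", "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
                n_header += 1
            else:
                break
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise DemFormatError(f"ESRI ASCII grid missing {key!r} in {path}")
    cell = header["cellsize"]
    if "xllcorner" in header:
        xll, yll = header["xllcorner"], header["yllcorner"]
    elif "xllcenter" in header:
        xll = header["xllcenter"] - cell / 2.0
        yll = header["yllcenter"] - cell / 2.0
    else:
        raise DemFormatError(f"ESRI ASCII grid missing corner/centre origin in {path}")
    elev = np.loadtxt(path, skiprows=n_header, ndmin=2)
    if elev.shape != (int(header["nrows"]), int(header["ncols"])):
        raise DemFormatError(
            f"grid shape {elev.shape} does not match header "
            f"({int(header['nrows'])}, {int(header['ncols'])}) in {path}"
        )
    nodata = header.get("nodata_value", -9999.0)
    elev = np.where(elev == nodata, np.nan, elev)
    return DemGrid(xll=xll, yll=yll, cell=cell, elev=elev, nodata=nodata)


def write_esri_ascii(dem: DemGrid, path) -> None:
    z = np.where(np.isfinite(dem.elev), dem.elev, dem.nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {dem.n_cols}\n")
        fh.write(f"nrows {dem.n_rows}\n")
        fh.write(f"xllcorner {dem.xll:.6f}\n")
        fh.write(f"yllcorner {dem.yll:.6f}\n")
        fh.write(f"cellsize {dem.cell:.6f}\n")
        fh.write(f"NODATA_value {dem.nodata:g}\n")
        np.savetxt(fh, z, fmt="%.6f")


_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42112


def write_geotiff(dem: DemGrid, path) -> None:
    """Write the elevation grid as a single-band float32 GeoTIFF.

    Georeferencing is carried by the ModelPixelScale and ModelTiepoint tags
    (raster origin = outer corner of the top-left cell).
    """
    import tifffile

    top_left_y = dem.yll + dem.n_rows * dem.cell
    z = np.where(np.isfinite(dem.elev), dem.elev, dem.nodata).astype(np.float32)
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (dem.cell, dem.cell, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, dem.xll, top_left_y, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, f"{dem.nodata:g}"),
    ]
    tifffile.imwrite(path, z, extratags=extratags)


def read_geotiff(path) -> DemGrid:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        tags = page.tags
        if _TAG_MODEL_PIXEL_SCALE not in tags or _TAG_MODEL_TIEPOINT not in tags:
            raise DemFormatError(f"GeoTIFF {path} has no georeferencing tags")
        scale = tags[_TAG_MODEL_PIXEL_SCALE].value
        tie = tags[_TAG_MODEL_TIEPOINT].value
        nodata = -9999.0
        if _TAG_GDAL_NODATA in tags:
            nodata = float(tags[_TAG_GDAL_NODATA].value)
        elev = page.asarray().astype(float)
    if abs(scale[0] - scale[1]) > 1e-9:
        raise DemFormatError("non-square cells are not supported")
    cell = float(scale[0])
    # tie point maps raster (col tie[0], row tie[1]) to model (tie[3], tie[4])
    top_left_x = tie[3] - tie[0] * cell
    top_left_y = tie[4] + tie[1] * cell
    xll = top_left_x
    yll = top_left_y - elev.shape[0] * cell
    elev = np.where(elev == nodata, np.nan, elev)
    return DemGrid(xll=xll, yll=yll, cell=cell, elev=elev, nodata=nodata)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def annotate_fixes(
    fixes: pd.DataFrame,
    dem: DemGrid,
    method: str = "nearest",
    max_outside_frac: float = 0.05,
) -> pd.DataFrame:
    """Attach elevation, slope and aspect to every fix.

    ``method`` selects elevation sampling: ``nearest`` (default) looks up the
    enclosing cell; ``bilinear`` interpolates elevation from the four
    surrounding cell centres (slope/aspect stay nearest-cell).  Fixes outside
    the DEM extent get NaN annotations; if more than ``max_outside_frac`` of
    fixes fall outside, that is treated as an extent mismatch and raised.
    """
    if dem.slope_deg is None:
        compute_slope_aspect(dem)
    out = fixes.copy()
    x = out["x"].to_numpy(float)
    y = out["y"].to_numpy(float)
    inside = dem.contains(x, y)
    n_out = int((~inside).sum())
    if len(out) and n_out / len(out) > max_outside_frac:
        raise ValueError(
            f"{n_out}/{len(out)} fixes fall outside the DEM extent "
            f"{dem.extent}; fixes and DEM do not match"
        )
    if n_out:
        log.warning("%d fixes outside DEM extent flagged as nodata", n_out)
    row, col = dem.index_of(x, y)
    if method == "nearest":
        elev = dem.elev[row, col]
    elif method == "bilinear":
        elev = _bilinear(dem, x, y)
    else:
        raise ValueError(f"unknown sampling method {method!r}")
    elev = np.where(inside, elev, np.nan)
    out["elevation"] = elev
    out["slope_deg"] = np.where(inside, dem.slope_deg[row, col], np.nan)
    out["slope_pct"] = np.where(inside, dem.slope_pct[row, col], np.nan)
    out["aspect_deg"] = np.where(inside, dem.aspect_deg[row, col], np.nan)
    out.attrs["dem_sampling"] = method
    out.attrs["aspect_convention"] = "degrees clockwise from north, NaN = flat"
    return out


def _bilinear(dem: DemGrid, x, y):
    # fractional position in cell-centre coordinates
    fx = (np.asarray(x) - dem.xll) / dem.cell - 0.5
    fy = (dem.yll + dem.n_rows * dem.cell - np.asarray(y)) / dem.cell - 0.5
    c0 = np.clip(np.floor(fx).astype(int), 0, dem.n_cols - 2)
    r0 = np.clip(np.floor(fy).astype(int), 0, dem.n_rows - 2)
    tx = np.clip(fx - c0, 0.0, 1.0)
    ty = np.clip(fy - r0, 0.0, 1.0)
    z = dem.elev
    return (
        z[r0, c0] * (1 - tx) * (1 - ty)
        + z[r0, c0 + 1] * tx * (1 - ty)
        + z[r0 + 1, c0] * (1 - tx) * ty
        + z[r0 + 1, c0 + 1] * tx * ty
    )
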