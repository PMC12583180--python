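"""Core raster data model and spatial primitives.

A :class:`Grid` is a single georeferenced 2-D layer: a value array with row 0
at the northern edge, an affine transform (pixel-center registration), and a
boolean nodata mask that every operation propagates.  A :class:`GridStack` is
a time-ordered sequence of co-registered grids.  On-disk formats are
single-band GeoTIFF (via tifffile, with ModelPixelScale / ModelTiepoint /
GDAL_NODATA tags) and a diffable plain-text CSV dialect used for fixtures.

All layers in an analysis are expected to share one master geometry; the
:func:`align_resample` and :func:`idw_interpolate` helpers bring foreign
layers onto it.  Cell area is treated as nominal ``cell_width x cell_height``
(no geodesic correction).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile
from scipy.spatial import cKDTree

__all__ = [
    "GridTransform",
    "Grid",
    "ClassifiedGrid",
    "GridStack",
    "PointSamples",
    "read_grid",
    "write_grid",
    "align_resample",
    "idw_interpolate",
    "slope_aspect",
]

# TIFF tag codes used for georeferencing
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113

DEFAULT_NODATA = -9999.0


@dataclass(frozen=True)
class GridTransform:
    """Affine mapping between pixel indices and projected coordinates.

    ``x_origin``/``y_origin`` are the projected coordinates of the *outer
    corner* of the top-left pixel; ``dx``/``dy`` are strictly positive cell
    sizes.  Row 0 is the northernmost row, so y decreases with row index.
    Pixel centers sit half a cell inside the corner.
    """

    x_origin: float
    y_origin: float
    dx: float
    dy: float

    def __post_init__(self) -> None:
        if not (self.dx > 0 and self.dy > 0):
            raise ValueError("cell sizes dx and dy must be strictly positive")

    def xy(self, row, col):
        """Projected center coordinates of pixel (row, col)."""
        x = self.x_origin + (np.asarray(col, dtype=float) + 0.5) * self.dx
        y = self.y_origin - (np.asarray(row, dtype=float) + 0.5) * self.dy
        return x, y

    def rowcol_float(self, x, y):
        """Fractional (row, col) such that integer values land on centers."""
        col = (np.asarray(x, dtype=float) - self.x_origin) / self.dx - 0.5
        row = (self.y_origin - np.asarray(y, dtype=float)) / self.dy - 0.5
        return row, col


@dataclass
class Grid:
    values: np.ndarray
    transform: GridTransform
    nodata_mask: np.ndarray = None
    units: str = ""
    crs_tag: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("Grid values must be a 2-D array")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape, dtype=bool)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.values.shape:
            raise ValueError("values and nodata_mask must have identical shape")

    @property
    def shape(self):
        return self.values.shape

    @property
    def cell_area(self) -> float:
        return self.transform.dx * self.transform.dy

    def masked(self) -> np.ma.MaskedArray:
        return np.ma.MaskedArray(self.values, mask=self.nodata_mask)

    def with_values(self, values, extra_mask=None) -> "Grid":
        """New Grid on the same geometry; mask is propagated (ORed)."""
        mask = self.nodata_mask.copy()
        if extra_mask is not None:
            mask |= np.asarray(extra_mask, dtype=bool)
        return Grid(np.asarray(values), self.transform, mask,
                    units=self.units, crs_tag=self.crs_tag)

    def same_geometry(self, other: "Grid") -> bool:
        return self.shape == other.shape and self.transform == other.transform


@dataclass
class ClassifiedGrid:
    """Integer-labelled Grid plus a class dictionary {code: label}.

    Codes of masked cells are meaningless; consumers must honour the mask.
    """

    grid: Grid
    classes: dict

    def __post_init__(self) -> None:
        if not np.issubdtype(np.asarray(self.grid.values).dtype, np.integer):
            raise ValueError("ClassifiedGrid requires integer-coded values")
        present = np.unique(self.grid.values[~self.grid.nodata_mask])
        unknown = [int(c) for c in present if int(c) not in self.classes]
        if unknown:
            raise ValueError(f"class codes {unknown} missing from class dictionary")

    @property
    def labels(self):
        return [self.classes[c] for c in sorted(self.classes)]

    @property
    def codes(self):
        return sorted(self.classes)

    def area_km2(self, cell_area_km2: float) -> dict:
        """Unmasked area per class, in km^2."""
        vals = self.grid.values[~self.grid.nodata_mask]
        return {c: float(np.count_nonzero(vals == c) * cell_area_km2)
                for c in self.codes}


@dataclass
class GridStack:
    """Time-ordered sequence of co-registered grids.

    ``timestamps`` are ``(year,)`` or ``(year, period)`` tuples and must be
    strictly increasing in lexicographic order.
    """

    grids: list
    timestamps: list

    def __post_init__(self) -> None:
        if len(self.grids) != len(self.timestamps):
            raise ValueError("grids and timestamps must have equal length")
        if not self.grids:
            raise ValueError("GridStack must hold at least one grid")
        self.timestamps = [t if isinstance(t, tuple) else (t,) for t in self.timestamps]
        g0 = self.grids[0]
        for g in self.grids[1:]:
            if not g0.same_geometry(g):
                raise ValueError("all grids in a stack must share shape and transform")
        for a, b in zip(self.timestamps, self.timestamps[1:]):
            if not a < b:
                raise ValueError(f"timestamps must be strictly increasing, got {a} !< {b}")

    def __len__(self) -> int:
        return len(self.grids)

    def __iter__(self):
        return iter(self.grids)

    @property
    def years(self):
        return sorted({t[0] for t in self.timestamps})

    def values_3d(self) -> np.ma.MaskedArray:
        """(time, rows, cols) masked array view of the stack."""
        data = np.stack([g.values for g in self.grids])
        mask = np.stack([g.nodata_mask for g in self.grids])
        return np.ma.MaskedArray(data, mask=mask)

    def select(self, predicate) -> "GridStack":
        keep = [(g, t) for g, t in zip(self.grids, self.timestamps) if predicate(t)]
        if not keep:
            raise ValueError("selection matched no layers")
        return GridStack([g for g, _ in keep], [t for _, t in keep])


@dataclass
class PointSamples:
    """Irregular point observations (projected x, y, value)."""

    x: np.ndarray
    y: np.ndarray
    value: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.atleast_1d(np.asarray(self.x, dtype=float))
        self.y = np.atleast_1d(np.asarray(self.y, dtype=float))
        self.value = np.atleast_1d(np.asarray(self.value, dtype=float))
        if not (len(self.x) == len(self.y) == len(self.value)):
            raise ValueError("x, y and value must have equal length")
        if len(self.x) < 1:
            raise ValueError("PointSamples needs at least one record")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))
                and np.all(np.isfinite(self.value))):
            raise ValueError("PointSamples coordinates and values must be finite")

    def __len__(self) -> int:
        return len(self.x)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_CSV_MAGIC = "# vegdyn-grid"


def write_grid(grid: Grid, path: str, nodata: float = DEFAULT_NODATA) -> None:
    """Write a Grid as single-band GeoTIFF or (``.csv``) the text dialect.

    Masked cells are stored as ``nodata``.  Integer arrays keep their dtype;
    float arrays are stored at float64 so round-trips are lossless to well
    below 1e-6.
    """
    if str(path).lower().endswith(".csv"):
        _write_grid_csv(grid, path, nodata)
        return
    values = np.array(grid.values, copy=True)
    if np.issubdtype(values.dtype, np.integer):
        values[grid.nodata_mask] = int(nodata)
    else:
        values = values.astype(np.float64)
        values[grid.nodata_mask] = float(nodata)
    t = grid.transform
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (t.dx, t.dy, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, t.x_origin, t.y_origin, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, str(nodata)),
    ]
    tifffile.imwrite(path, values, extratags=extratags,
                     metadata=None, description=grid.crs_tag or None)


def read_grid(path: str) -> Grid:
    """Read a single-band GeoTIFF or CSV-dialect grid from ``path``."""
    if not os.path.exists(path):
        raise FileNotFoundError(f"raster file not found: {path}")
    if str(path).lower().endswith(".csv"):
        return _read_grid_csv(path)
    with tifffile.TiffFile(path) as tif:
        if len(tif.pages) != 1:
            raise ValueError(f"{path}: expected a single-band raster, "
                             f"found {len(tif.pages)} pages")
        page = tif.pages[0]
        values = page.asarray()
        if values.ndim != 2:
            raise ValueError(f"{path}: expected a single-band raster, "
                             f"got array of shape {values.shape}")
        tags = page.tags
        if _TAG_MODEL_PIXEL_SCALE not in tags or _TAG_MODEL_TIEPOINT not in tags:
            raise ValueError(f"{path}: missing geotransform tags")
        scale = tags[_TAG_MODEL_PIXEL_SCALE].value
        tie = tags[_TAG_MODEL_TIEPOINT].value
        transform = GridTransform(float(tie[3]), float(tie[4]),
                                  float(scale[0]), float(scale[1]))
        mask = np.zeros(values.shape, dtype=bool)
        if _TAG_GDAL_NODATA in tags:
            nodata = float(tags[_TAG_GDAL_NODATA].value)
            mask = values == values.dtype.type(nodata)
        crs_tag = page.description or ""
    return Grid(values, transform, mask, crs_tag=crs_tag)


def _write_grid_csv(grid: Grid, path: str, nodata: float) -> None:
    t = grid.transform
    rows, cols = grid.shape
    values = grid.values.astype(np.float64).copy()
    values[grid.nodata_mask] = nodata
    with open(path, "w") as fh:
        fh.write(f"{_CSV_MAGIC}\n")
        fh.write(f"# shape: {rows} {cols}\n")
        fh.write(f"# transform: {t.x_origin!r} {t.y_origin!r} {t.dx!r} {t.dy!r}\n")
        fh.write(f"# nodata: {nodata!r}\n")
        fh.write(f"# units: {grid.units}\n")
        fh.write(f"# crs: {grid.crs_tag}\n")
        for r in range(rows):
            fh.write(",".join(repr(float(v)) for v in values[r]) + "\n")


def _read_grid_csv(path: str) -> Grid:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != _CSV_MAGIC:
        raise ValueError(f"{path}: not a vegdyn grid CSV (missing magic header)")
    header = {}
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            if ":" in line:
                key, _, rest = line[1:].partition(":")
                header[key.strip()] = rest.strip()
            body_start = i + 1
        else:
            break
    if "transform" not in header or "shape" not in header:
        raise ValueError(f"{path}: grid CSV missing shape/transform header")
    x0, y0, dx, dy = (float(v) for v in header["transform"].split())
    nodata = float(header.get("nodata", DEFAULT_NODATA))
    rows, cols = (int(v) for v in header["shape"].split())
    values = np.array(
        [[float(v) for v in line.split(",")] for line in lines[body_start:body_start + rows]]
    )
    if values.shape != (rows, cols):
        raise ValueError(f"{path}: body shape {values.shape} != declared {(rows, cols)}")
    mask = values == nodata
    return Grid(values, GridTransform(x0, y0, dx, dy), mask,
                units=header.get("units", ""), crs_tag=header.get("crs", ""))


# ---------------------------------------------------------------------------
# Resampling and interpolation
# ---------------------------------------------------------------------------

def _target_geometry(target):
    """Accept a Grid or a (shape, GridTransform) pair as target geometry."""
    if isinstance(target, Grid):
        return target.shape, target.transform
    shape, transform = target
    return tuple(shape), transform


def align_resample(grid: Grid, target, method: str = "bilinear",
                   categorical: bool = False) -> Grid:
    """Resample ``grid`` onto a target geometry.

    ``method='nearest'`` snaps each target cell center to the nearest source
    cell (mandatory for categorical layers; never invents labels).
    ``method='bilinear'`` is a convex combination of the four surrounding
    source cell centers; it is refused when ``categorical`` is set.  Target
    centers outside the source extent, and bilinear neighbourhoods touching a
    masked source cell, come out masked.
    """
    if method not in ("nearest", "bilinear"):
        raise ValueError(f"unknown resampling method {method!r}")
    if categorical and method == "bilinear":
        raise ValueError("bilinear resampling is not allowed on categorical layers")
    shape, transform = _target_geometry(target)
    rows_t, cols_t = shape
    tr, tc = np.meshgrid(np.arange(rows_t), np.arange(cols_t), indexing="ij")
    x, y = transform.xy(tr, tc)
    frow, fcol = grid.transform.rowcol_float(x, y)
    nrows, ncols = grid.shape

    # spatial overlap: at least one target center must fall inside the source
    inside = (frow >= -0.5) & (frow <= nrows - 0.5) & (fcol >= -0.5) & (fcol <= ncols - 0.5)
    if not inside.any():
        raise ValueError("source and target geometries do not overlap")

    if method == "nearest":
        r = np.clip(np.rint(frow).astype(int), 0, nrows - 1)
        c = np.clip(np.rint(fcol).astype(int), 0, ncols - 1)
        out = grid.values[r, c]
        mask = grid.nodata_mask[r, c] | ~inside
    else:
        frow_c = np.clip(frow, 0.0, nrows - 1.0)
        fcol_c = np.clip(fcol, 0.0, ncols - 1.0)
        r0 = np.floor(frow_c).astype(int)
        c0 = np.floor(fcol_c).astype(int)
        r1 = np.minimum(r0 + 1, nrows - 1)
        c1 = np.minimum(c0 + 1, ncols - 1)
        wr = frow_c - r0
        wc = fcol_c - c0
        v = grid.values.astype(float)
        out = ((1 - wr) * (1 - wc) * v[r0, c0] + (1 - wr) * wc * v[r0, c1]
               + wr * (1 - wc) * v[r1, c0] + wr * wc * v[r1, c1])
        m = grid.nodata_mask
        mask = m[r0, c0] | m[r0, c1] | m[r1, c0] | m[r1, c1] | ~inside
    return Grid(out, transform, mask, units=grid.units, crs_tag=grid.crs_tag)


def idw_interpolate(samples: PointSamples, target, power: float = 2.0,
                    k_neighbors: int = 12, eps: float = 1e-9) -> Grid:
    """Inverse-distance-weighted interpolation of points onto a grid.

    Each cell takes ``sum(w_i v_i)/sum(w_i)`` over its ``k_neighbors`` nearest
    samples with ``w_i = d_i**-power``; a cell whose center coincides with a
    sample (distance < ``eps``) returns that sample's value exactly.
    """
    if power <= 0:
        raise ValueError("IDW power must be strictly positive")
    shape, transform = _target_geometry(target)
    rows, cols = shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    x, y = transform.xy(rr, cc)
    pts = np.column_stack([samples.x, samples.y])
    k = min(int(k_neighbors), len(samples))
    if k < 1:
        raise ValueError("k_neighbors must be >= 1")
    tree = cKDTree(pts)
    dist, idx = tree.query(np.column_stack([x.ravel(), y.ravel()]), k=k)
    dist = np.atleast_2d(dist.reshape(-1, k))
    idx = idx.reshape(-1, k)
    vals = samples.value[idx]
    exact = dist[:, 0] < eps
    with np.errstate(divide="ignore"):
        w = dist ** (-float(power))
    w[~np.isfinite(w)] = 0.0
    out = np.einsum("ij,ij->i", w, vals) / np.maximum(w.sum(axis=1), 1e-300)
    out[exact] = vals[exact, 0]
    return Grid(out.reshape(rows, cols), transform)


# ---------------------------------------------------------------------------
# DEM derivatives
# ---------------------------------------------------------------------------

def slope_aspect(dem: Grid, flat_threshold: float = 0.5):
    """Horn 3x3 slope (degrees) and aspect (degrees clockwise from north).

    Aspect is the compass direction the surface *faces* (downslope direction);
    cells with slope below ``flat_threshold`` degrees are coded -1 (flat).
    Edges are handled by replication; masked cells propagate to any derivative
    touching them.
    """
    if dem.shape[0] < 3 or dem.shape[1] < 3:
        raise ValueError("slope_aspect requires a DEM of at least 3x3 cells")
    z = np.pad(dem.values.astype(float), 1, mode="edge")
    dx, dy = dem.transform.dx, dem.transform.dy
    # Horn weights; rows run north -> south
    nw, n_, ne = z[:-2, :-2], z[:-2, 1:-1], z[:-2, 2:]
    w_, e_ = z[1:-1, :-2], z[1:-1, 2:]
    sw, s_, se = z[2:, :-2], z[2:, 1:-1], z[2:, 2:]
    dz_dx = ((ne + 2 * e_ + se) - (nw + 2 * w_ + sw)) / (8.0 * dx)
    dz_dy = ((nw + 2 * n_ + ne) - (sw + 2 * s_ + se)) / (8.0 * dy)  # +y = north
    slope = np.degrees(np.arctan(np.hypot(dz_dx, dz_dy)))
    # downslope (facing) direction: azimuth of -gradient, north=0, east=90
    aspect = np.degrees(np.arctan2(-dz_dx, -dz_dy)) % 360.0
    aspect[slope < flat_threshold] = -1.0
    # mask wherever the 3x3 window touched a masked cell
    m = np.pad(dem.nodata_mask, 1, mode="edge")
    touched = np.zeros(dem.shape, dtype=bool)
    for dr in (0, 1, 2):
        for dc in (0, 1, 2):
            touched |= m[dr:dr + dem.shape[0], dc:dc + dem.shape[1]]
    slope_grid = Grid(slope, dem.transform, touched.copy(), units="deg",
                      crs_tag=dem.crs_tag)
    aspect_grid = Grid(aspect, dem.transform, touched.copy(), units="deg",
                       crs_tag=dem.crs_tag)
    return slope_grid, aspect_grid
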