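"""Environmental raster layers: I/O, co-registration, z-scoring, centroid sampling.

Layers are lightweight in-memory rasters on a regular north-up grid in a
metre-based CRS (spherical Web Mercator, EPSG:3857, by default).  Missing
cells (open water, out-of-footprint) are NaN internally and a nodata sentinel
on disk.  On-disk format is the plain-text ESRI ASCII grid, which any GIS
reads natively.

The climatic moisture index (CMI) is the water-balance difference P − PET;
temperature and CMI enter the ecozone model as multiannual means, and all
three predictors are z-scored over valid cells before clustering so that
elevation, temperature and moisture contribute on a common scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "EnvLayer",
    "EnvStack",
    "CentroidSample",
    "read_ascii_grid",
    "write_ascii_grid",
    "derive_cmi",
    "multiannual_mean",
    "aggregate_and_align",
    "zscore_normalize",
    "sample_centroids",
    "lonlat_to_mercator",
    "mercator_to_lonlat",
]

LAYER_KINDS = ("elevation", "temperature", "cmi", "precipitation", "pet")

# Spherical Web-Mercator (EPSG:3857) earth radius, metres.
_R_MERC = 6378137.0


def lonlat_to_mercator(lon, lat):
    """WGS84 lon/lat (degrees) → EPSG:3857 x/y (metres)."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    x = _R_MERC * np.radians(lon)
    y = _R_MERC * np.log(np.tan(np.pi / 4.0 + np.radians(lat) / 2.0))
    return x, y


def mercator_to_lonlat(x, y):
    """EPSG:3857 x/y (metres) → WGS84 lon/lat (degrees)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    lon = np.degrees(x / _R_MERC)
    lat = np.degrees(2.0 * np.arctan(np.exp(y / _R_MERC)) - np.pi / 2.0)
    return lon, lat


@dataclass
class EnvLayer:
    """One georeferenced raster layer (north-up regular grid).

    ``xmin``/``ymax`` locate the outer corner of the top-left cell; ``dx``,
    ``dy`` are positive cell sizes in CRS units (metres for EPSG:3857).
    ``data`` holds float values with NaN marking missing cells.
    """

    kind: str
    data: np.ndarray
    xmin: float
    ymax: float
    dx: float
    dy: float
    crs: str = "EPSG:3857"
    nodata: float = -99999.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("layer data must be 2-D")
        if self.dx <= 0 or self.dy <= 0:
            raise ValueError("cell sizes must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax)."""
        nrows, ncols = self.shape
        return (self.xmin, self.ymax - nrows * self.dy, self.xmin + ncols * self.dx, self.ymax)

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.data)

    def x_centers(self) -> np.ndarray:
        return self.xmin + (np.arange(self.shape[1]) + 0.5) * self.dx

    def y_centers(self) -> np.ndarray:
        return self.ymax - (np.arange(self.shape[0]) + 0.5) * self.dy

    def index_of(self, x, y):
        """(row, col) of the cell containing metric point(s) (x, y)."""
        col = np.floor((np.asarray(x, dtype=float) - self.xmin) / self.dx).astype(int)
        row = np.floor((self.ymax - np.asarray(y, dtype=float)) / self.dy).astype(int)
        return row, col

    def same_grid(self, other: "EnvLayer", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and self.crs == other.crs
            and abs(self.xmin - other.xmin) < tol
            and abs(self.ymax - other.ymax) < tol
            and abs(self.dx - other.dx) < tol
            and abs(self.dy - other.dy) < tol
        )


# ---------------------------------------------------------------------------
# ASCII-grid I/O
# ---------------------------------------------------------------------------


def write_ascii_grid(layer: EnvLayer, path) -> None:
    """Write a layer as an ESRI ASCII grid (requires square cells)."""
    if not math.isclose(layer.dx, layer.dy):
        raise ValueError("ESRI ASCII grids require square cells")
    nrows, ncols = layer.shape
    yll = layer.ymax - nrows * layer.dy
    data = np.where(np.isfinite(layer.data), layer.data, layer.nodata)
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {layer.xmin!r}\n"
        f"yllcorner {yll!r}\n"
        f"cellsize {layer.dx!r}\n"
        f"NODATA_value {layer.nodata!r}\n"
    )
    with open(path, "w", encoding="ascii") as fh:
        fh.write(header)
        np.savetxt(fh, data, fmt="%.10g")


def read_ascii_grid(path, kind: str = "elevation", crs: str = "EPSG:3857") -> EnvLayer:
    """Read an ESRI ASCII grid into an :class:`EnvLayer`."""
    header: dict[str, float] = {}
    with open(path, "r", encoding="ascii") as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)
    nodata = header.get("nodata_value", -99999.0)
    data = np.where(data == nodata, np.nan, data)
    cell = header["cellsize"]
    return EnvLayer(
        kind=kind,
        data=data,
        xmin=header["xllcorner"],
        ymax=header["yllcorner"] + header["nrows"] * cell,
        dx=cell,
        dy=cell,
        crs=crs,
        nodata=nodata,
    )


# ---------------------------------------------------------------------------
# Derivations and normalisation
# ---------------------------------------------------------------------------


def derive_cmi(p: EnvLayer, pet: EnvLayer) -> EnvLayer:
    """Climatic moisture index as the water balance CMI = P − PET.

    Nodata in either input propagates to the output.
    """
    if not p.same_grid(pet):
        raise ValueError("precipitation and PET layers are not co-registered")
    return replace(p, kind="cmi", data=p.data - pet.data)


def multiannual_mean(layers: Sequence[EnvLayer], kind: str | None = None) -> EnvLayer:
    """Unweighted cell-wise mean of monthly layers (e.g. 468 months → one grid)."""
    if not layers:
        raise ValueError("no layers to average")
    first = layers[0]
    for lyr in layers[1:]:
        if not first.same_grid(lyr):
            raise ValueError("monthly layers are not co-registered")
    stack = np.stack([lyr.data for lyr in layers])
    return replace(first, kind=kind or first.kind, data=np.nanmean(stack, axis=0))


def aggregate_and_align(
    layer: EnvLayer,
    resolution: float,
    extent: tuple[float, float, float, float] | None = None,
) -> EnvLayer:
    """Resample a layer onto a target grid by bilinear interpolation.

    ``extent`` is (xmin, ymin, xmax, ymax) in the layer CRS; defaults to the
    layer's own bounds.  Bilinear resampling preserves constant and affine
    fields away from edges; any NaN touching a target cell's support makes
    the output cell NaN (conservative nodata propagation).
    """
    xmin0, ymin0, xmax0, ymax0 = extent or layer.bounds
    ncols = int(round((xmax0 - xmin0) / resolution))
    nrows = int(round((ymax0 - ymin0) / resolution))
    if ncols <= 0 or nrows <= 0:
        raise ValueError("requested extent has no overlap at this resolution")
    xc = xmin0 + (np.arange(ncols) + 0.5) * resolution
    yc = ymax0 - (np.arange(nrows) + 0.5) * resolution
    # fractional source indices of target cell centres
    ci = (xc - layer.xmin) / layer.dx - 0.5
    ri = (layer.ymax - yc) / layer.dy - 0.5
    rr, cc = np.meshgrid(ri, ci, indexing="ij")
    out = ndimage.map_coordinates(
        layer.data, [rr, cc], order=1, mode="nearest", cval=np.nan
    )
    # map_coordinates propagates NaN through the bilinear stencil already;
    # mask cells whose centres fall outside the source footprint
    outside = (rr < -0.5) | (rr > layer.shape[0] - 0.5) | (cc < -0.5) | (cc > layer.shape[1] - 0.5)
    out[outside] = np.nan
    return replace(layer, data=out, xmin=xmin0, ymax=ymax0, dx=resolution, dy=resolution)


def zscore_normalize(layer: EnvLayer) -> EnvLayer:
    """Standardise a layer to zero mean and unit (population) SD over valid cells."""
    valid = layer.valid_mask
    if valid.sum() < 2:
        raise ValueError("need at least 2 valid cells to z-score")
    mu = float(np.mean(layer.data[valid]))
    sd = float(np.std(layer.data[valid]))  # population sd, ddof=0
    if sd == 0.0:
        raise ValueError("cannot z-score a constant layer (sd = 0)")
    return replace(layer, data=(layer.data - mu) / sd)


# ---------------------------------------------------------------------------
# Stack + centroid sampling
# ---------------------------------------------------------------------------


@dataclass
class EnvStack:
    """Three co-registered z-scored predictor layers: elevation, temperature, CMI."""

    elevation: EnvLayer
    temperature: EnvLayer
    cmi: EnvLayer

    def __post_init__(self) -> None:
        if not (
            self.elevation.same_grid(self.temperature)
            and self.elevation.same_grid(self.cmi)
        ):
            raise ValueError("stack layers must share grid, extent and CRS")

    @property
    def layers(self) -> tuple[EnvLayer, EnvLayer, EnvLayer]:
        return (self.elevation, self.temperature, self.cmi)

    @property
    def valid_mask(self) -> np.ndarray:
        return (
            self.elevation.valid_mask
            & self.temperature.valid_mask
            & self.cmi.valid_mask
        )

    @property
    def grid(self) -> EnvLayer:
        """The reference layer carrying the shared georeference."""
        return self.elevation

    def values_at(self, x, y) -> np.ndarray:
        """(n, 3) array of (elev, tmp, cmi) by nearest-cell lookup; NaN outside."""
        row, col = self.grid.index_of(x, y)
        row, col = np.atleast_1d(row).ravel(), np.atleast_1d(col).ravel()
        nrows, ncols = self.grid.shape
        inside = (row >= 0) & (row < nrows) & (col >= 0) & (col < ncols)
        out = np.full((row.size, 3), np.nan)
        for j, lyr in enumerate(self.layers):
            out[inside, j] = lyr.data[row[inside], col[inside]]
        return out

    @classmethod
    def from_raw_layers(cls, elevation: EnvLayer, temperature: EnvLayer, cmi: EnvLayer) -> "EnvStack":
        """Z-score three co-registered raw layers and assemble the stack."""
        return cls(
            elevation=zscore_normalize(elevation),
            temperature=zscore_normalize(temperature),
            cmi=zscore_normalize(cmi),
        )


@dataclass
class CentroidSample:
    """Regular-lattice point sample of the stack (NA points retained, not dropped)."""

    x: np.ndarray
    y: np.ndarray
    values: np.ndarray  # (n, 3): elev_z, tmp_z, cmi_z; NaN row = NA marker
    spacing: float

    @property
    def is_na(self) -> np.ndarray:
        return ~np.all(np.isfinite(self.values), axis=1)

    def __len__(self) -> int:
        return int(self.x.size)


def sample_centroids(stack: EnvStack, spacing: float, land_buffer=None) -> CentroidSample:
    """Sample the stack at the centroids of a regular ``spacing``-metre lattice.

    Points over missing cells carry the NA marker rather than being dropped,
    so the later clustering step can keep a reserved unclassified class with
    correct geography.  ``land_buffer`` (a shapely polygon in stack CRS)
    restricts the lattice to land; by default the full extent is used.
    """
    xmin, ymin, xmax, ymax = stack.grid.bounds
    nx = int(math.floor((xmax - xmin) / spacing))
    ny = int(math.floor((ymax - ymin) / spacing))
    if nx <= 0 or ny <= 0:
        raise ValueError("extent smaller than lattice spacing")
    xs = xmin + (np.arange(nx) + 0.5) * spacing
    ys = ymax - (np.arange(ny) + 0.5) * spacing
    xx, yy = np.meshgrid(xs, ys)
    x, y = xx.ravel(), yy.ravel()
    if land_buffer is not None:
        from shapely import points, contains

        keep = contains(land_buffer, points(np.column_stack([x, y])))
        if not keep.any():
            raise ValueError("land buffer does not intersect the stack extent")
        x, y = x[keep], y[keep]
    vals = stack.values_at(x, y)
    return CentroidSample(x=x, y=y, values=vals, spacing=spacing)
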