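"""Georeferenced raster I/O and polygon clipping.

Rasters are GeoTIFFs read and written through :mod:`tifffile`, carrying the
standard geo tags (ModelPixelScale, ModelTiepoint, GeoKeyDirectory) plus the
GDAL nodata tag. Only north-up, axis-aligned rasters are supported — the
orthomosaic products this package consumes are always resampled to that
orientation by the photogrammetry stage.

Conventions fixed here and relied on everywhere else:

* band indices are 1-based at the API surface;
* raster and ROI coordinate reference systems must match exactly (no
  silent reprojection);
* a pixel belongs to a polygon iff its *center* is inside or on the
  boundary of the polygon;
* nodata in any referenced band makes that pixel missing downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
import tifffile
from shapely.geometry import Polygon

__all__ = [
    "CANONICAL_BANDS",
    "BandMap",
    "CRSMismatchError",
    "GeoTransform",
    "RasterGrid",
    "clip_plot",
    "load_raster",
    "write_raster",
]

#: canonical spectral variable names usable in trait formulas
CANONICAL_BANDS = ("r", "g", "b", "re", "nir")

_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GEO_KEY_DIRECTORY = 34735
_TAG_GEO_ASCII_PARAMS = 34737
_TAG_GDAL_NODATA = 42113


class CRSMismatchError(ValueError):
    """Raster and vector coordinate reference systems differ."""


@dataclass(frozen=True)
class GeoTransform:
    """Affine map from pixel indices to world coordinates (north-up).

    ``origin_x``/``origin_y`` locate the *outer corner* of the top-left
    pixel. x grows with column, y shrinks with row.
    """

    origin_x: float
    origin_y: float
    pixel_width: float
    pixel_height: float  # positive; applied as -pixel_height per row

    def __post_init__(self) -> None:
        if self.pixel_width <= 0 or self.pixel_height <= 0:
            raise ValueError("pixel sizes must be positive (invertible geotransform)")

    def pixel_center(self, col, row):
        """World coordinates of the center of pixel ``(col, row)``."""
        x = self.origin_x + (np.asarray(col) + 0.5) * self.pixel_width
        y = self.origin_y - (np.asarray(row) + 0.5) * self.pixel_height
        return x, y

    def world_to_pixel(self, x: float, y: float) -> tuple[float, float]:
        """Fractional (col, row) of a world point."""
        col = (x - self.origin_x) / self.pixel_width
        row = (self.origin_y - y) / self.pixel_height
        return col, row

    def shifted(self, col0: int, row0: int) -> "GeoTransform":
        """Transform of a window whose top-left pixel is ``(col0, row0)``."""
        return GeoTransform(
            self.origin_x + col0 * self.pixel_width,
            self.origin_y - row0 * self.pixel_height,
            self.pixel_width,
            self.pixel_height,
        )


@dataclass
class RasterGrid:
    """A georeferenced multiband raster held in memory.

    ``values`` is shaped ``(n_bands, height, width)``. ``nodata`` may be
    ``None`` (fully valid raster) or a sentinel, NaN included.
    """

    values: np.ndarray
    transform: GeoTransform
    crs_id: str | None = None
    nodata: float | None = None
    warning: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim == 2:
            self.values = self.values[np.newaxis]
        if self.values.ndim != 3:
            raise ValueError("values must be 2-D (single band) or 3-D (bands, h, w)")
        if self.width <= 0 or self.height <= 0:
            raise ValueError("raster must have positive dimensions")

    @property
    def n_bands(self) -> int:
        return self.values.shape[0]

    @property
    def height(self) -> int:
        return self.values.shape[1]

    @property
    def width(self) -> int:
        return self.values.shape[2]

    @property
    def gsd(self) -> float:
        """Ground sampling distance in cm/pixel (world units are meters)."""
        return self.transform.pixel_width * 100.0

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        t = self.transform
        return (
            t.origin_x,
            t.origin_y - self.height * t.pixel_height,
            t.origin_x + self.width * t.pixel_width,
            t.origin_y,
        )

    def band(self, index: int) -> np.ndarray:
        """Band by 1-based index."""
        if not 1 <= index <= self.n_bands:
            raise IndexError(f"band index {index} > {self.n_bands} bands")
        return self.values[index - 1]

    def mask(self) -> np.ndarray:
        """Boolean (h, w) array, True where *any* band is nodata."""
        if self.nodata is None:
            return np.zeros((self.height, self.width), dtype=bool)
        if np.isnan(self.nodata):
            return np.isnan(self.values).any(axis=0)
        return (self.values == self.nodata).any(axis=0)

    def band_masked(self, index: int) -> np.ndarray:
        """Band as float with nodata pixels replaced by NaN."""
        out = self.band(index).astype(float, copy=True)
        out[self.mask()] = np.nan
        return out


@dataclass(frozen=True)
class BandMap:
    """Binding of canonical variable names to 1-based band indices."""

    sensor: str  # "RGB", "MS" or "OTHER"
    bindings: dict[str, int] = field(default_factory=dict)

    _REQUIRED = {"RGB": {"r", "g", "b"}, "MS": {"r", "g", "b", "re", "nir"}}

    def __post_init__(self) -> None:
        unknown = set(self.bindings) - set(CANONICAL_BANDS)
        if unknown:
            raise ValueError(f"unknown canonical band names: {sorted(unknown)}")
        indices = list(self.bindings.values())
        if len(indices) != len(set(indices)):
            raise ValueError("band map bindings must be injective")
        if any(i < 1 for i in indices):
            raise ValueError("band indices are 1-based")
        need = self._REQUIRED.get(self.sensor, set())
        missing = need - set(self.bindings)
        if missing:
            raise ValueError(f"sensor {self.sensor} requires bands {sorted(missing)}")

    @classmethod
    def rgb(cls, r: int = 1, g: int = 2, b: int = 3) -> "BandMap":
        return cls("RGB", {"r": r, "g": g, "b": b})

    @classmethod
    def ms(cls, r=1, g=2, b=3, re=4, nir=5) -> "BandMap":
        return cls("MS", {"r": r, "g": g, "b": b, "re": re, "nir": nir})

    def validate_against(self, raster: RasterGrid) -> None:
        bad = [(idx, name) for name, idx in self.bindings.items()
               if idx > raster.n_bands]
        if bad:
            idx, name = max(bad)
            raise ValueError(
                f"band index {idx} > {raster.n_bands} bands (binding {name!r})"
            )


def _geokey_directory(epsg: int) -> tuple[int, ...]:
    # version 1.1.0, two keys: model type (projected) + projected CS code
    return (1, 1, 0, 2, 1024, 0, 1, 1, 3072, 0, 1, epsg)


def write_raster(raster: RasterGrid, path) -> None:
    """Write a :class:`RasterGrid` as a GeoTIFF.

    Round-trips exactly through :func:`load_raster` for integer grids and
    to float precision for float grids.
    """
    path = Path(path)
    t = raster.transform
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, 12, 3, (t.pixel_width, t.pixel_height, 0.0)),
        (_TAG_MODEL_TIEPOINT, 12, 6, (0.0, 0.0, 0.0, t.origin_x, t.origin_y, 0.0)),
    ]
    if raster.nodata is not None:
        extratags.append((_TAG_GDAL_NODATA, 2, None, repr(float(raster.nodata))))
    if raster.crs_id:
        crs = raster.crs_id
        if crs.upper().startswith("EPSG:") and crs[5:].isdigit():
            keys = _geokey_directory(int(crs[5:]))
            extratags.append((_TAG_GEO_KEY_DIRECTORY, 3, len(keys), keys))
        else:
            extratags.append((_TAG_GEO_ASCII_PARAMS, 2, None, crs))
    data = np.moveaxis(raster.values, 0, -1)
    if data.shape[-1] == 1:
        data = data[..., 0]
    tifffile.imwrite(
        path,
        data,
        photometric="minisblack",
        planarconfig="contig" if data.ndim == 3 else None,
        extratags=extratags,
    )


def load_raster(path, band_map: BandMap | None = None) -> RasterGrid:
    """Read a georeferenced TIFF into a :class:`RasterGrid`.

    Raises ``ValueError`` naming the file when georeferencing tags are
    absent, and validates ``band_map`` indices against the band count.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray()
        tags = page.tags
        scale = tags.get(_TAG_MODEL_PIXEL_SCALE)
        tiepoint = tags.get(_TAG_MODEL_TIEPOINT)
        if scale is None or tiepoint is None:
            raise ValueError(f"{path}: no georeferencing (missing geo TIFF tags)")
        sx, sy = float(scale.value[0]), float(scale.value[1])
        i, j, _k, x, y, _z = (float(v) for v in tiepoint.value[:6])
        transform = GeoTransform(x - i * sx, y + j * sy, sx, sy)
        nodata = None
        nd_tag = tags.get(_TAG_GDAL_NODATA)
        if nd_tag is not None:
            nodata = float(str(nd_tag.value).strip())
        crs_id = None
        gk = tags.get(_TAG_GEO_KEY_DIRECTORY)
        if gk is not None:
            vals = list(gk.value)
            for k in range(4, len(vals), 4):
                key_id, _loc, _cnt, val = vals[k : k + 4]
                if key_id in (3072, 2048) and val not in (0, 32767):
                    crs_id = f"EPSG:{val}"
        if crs_id is None:
            ascii_tag = tags.get(_TAG_GEO_ASCII_PARAMS)
            if ascii_tag is not None:
                crs_id = str(ascii_tag.value).strip().rstrip("|\x00") or None
    if data.ndim == 3:
        data = np.moveaxis(data, -1, 0)
    raster = RasterGrid(data, transform, crs_id=crs_id, nodata=nodata)
    if band_map is not None:
        band_map.validate_against(raster)
    return raster


def _nodata_sentinel(values: np.ndarray, nodata: float | None) -> float:
    if nodata is not None:
        return nodata
    if np.issubdtype(values.dtype, np.floating):
        return float("nan")
    return float(np.iinfo(values.dtype).min)


def pixel_center_mask(raster: RasterGrid, polygon: Polygon) -> np.ndarray:
    """Boolean (h, w) array: pixel centers inside/on the polygon boundary."""
    cols = np.arange(raster.width)
    rows = np.arange(raster.height)
    cgrid, rgrid = np.meshgrid(cols, rows)
    xs, ys = raster.transform.pixel_center(cgrid, rgrid)
    # intersects == closed-boundary point-in-polygon
    return shapely.intersects_xy(polygon, xs, ys)


def clip_plot(raster: RasterGrid, roi) -> RasterGrid:
    """Clip a raster to one plot ROI.

    Returns the sub-raster over the ROI's bounding box with pixels whose
    centers fall outside the polygon set to nodata. ``roi`` is a
    ``PlotROI`` or a bare shapely polygon (then CRS checking is skipped).
    """
    polygon = getattr(roi, "polygon", roi)
    roi_crs = getattr(roi, "crs_id", None)
    if roi_crs is not None and raster.crs_id is not None and roi_crs != raster.crs_id:
        raise CRSMismatchError(
            f"CRS mismatch: raster {raster.crs_id!r} vs ROI {roi_crs!r}"
        )
    t = raster.transform
    minx, miny, maxx, maxy = polygon.bounds
    col0 = int(np.floor((minx - t.origin_x) / t.pixel_width))
    col1 = int(np.ceil((maxx - t.origin_x) / t.pixel_width))
    row0 = int(np.floor((t.origin_y - maxy) / t.pixel_height))
    row1 = int(np.ceil((t.origin_y - miny) / t.pixel_height))
    col0, row0 = max(col0, 0), max(row0, 0)
    col1, row1 = min(col1, raster.width), min(row1, raster.height)
    if col0 >= col1 or row0 >= row1:
        raise ValueError("ROI does not intersect the raster extent")

    window = raster.values[:, row0:row1, col0:col1]
    sub = RasterGrid(
        window.copy(),
        t.shifted(col0, row0),
        crs_id=raster.crs_id,
        nodata=raster.nodata,
    )
    inside = pixel_center_mask(sub, polygon)
    n_inside = int(inside.sum())
    sentinel = _nodata_sentinel(sub.values, sub.nodata)
    if not np.issubdtype(sub.values.dtype, np.floating) and np.isnan(sentinel):
        sub.values = sub.values.astype(float)
    sub.values[:, ~inside] = sentinel
    sub.nodata = sentinel
    if n_inside == 0:
        sub.warning = "no pixel centers inside polygon"
        warnings.warn(f"clip_plot: {sub.warning}", stacklevel=2)
    return sub
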