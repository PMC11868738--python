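"""Suitable-breeding-area construction from vegetation-index rasters.

The suitable area is defined empirically from index values (NDVI greenness,
SAR backscatter in dB) observed at nest sites: per-date values are
extracted at each nest, averaged per year, pooled across years, and the
5th/95th percentiles of the pooled per-nest means bound the "suitable"
index range. Cells of a year's mean raster inside the range form a binary
mask; yearly masks are compared via an overlap fraction, averaged across
years per index, and the union of the per-index areas is the final region
used for CSR simulation.

Rasters are square-cell, single-band grids in the same projected CRS as the
points. I/O uses the plain-text ESRI ASCII grid dialect; masks also export
as GeoJSON polygons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import MultiPolygon, Polygon

from .geometry import PointSet

__all__ = [
    "RasterGrid",
    "SuitabilityThresholds",
    "BinaryMask",
    "extract_at_points",
    "mean_over_dates",
    "percentile_thresholds",
    "threshold_mask",
    "overlap_fraction",
    "combine_masks",
    "mask_to_region",
    "mean_raster",
    "suitable_region_from_rasters",
]


@dataclass
class RasterGrid:
    """Single-band raster: ``values[row, col]`` with row 0 at the top.

    ``xmin``/``ymax`` give the world coordinate of the top-left corner;
    ``cell_size`` is the square cell edge in metres. Nodata is ``NaN``
    internally.
    """

    values: np.ndarray
    xmin: float
    ymax: float
    cell_size: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")

    @property
    def shape(self):
        return self.values.shape

    @property
    def bounds(self):
        ny, nx = self.values.shape
        return (self.xmin, self.ymax - ny * self.cell_size,
                self.xmin + nx * self.cell_size, self.ymax)

    def aligned_with(self, other: "RasterGrid") -> bool:
        return (self.values.shape == other.values.shape
                and np.isclose(self.xmin, other.xmin)
                and np.isclose(self.ymax, other.ymax)
                and np.isclose(self.cell_size, other.cell_size))

    def cell_of(self, x, y):
        """(row, col) of the cell containing each point."""
        col = np.floor((np.asarray(x, float) - self.xmin) / self.cell_size).astype(int)
        row = np.floor((self.ymax - np.asarray(y, float)) / self.cell_size).astype(int)
        return row, col

    def to_ascii(self, path, nodata: float = -9999.0) -> None:
        ny, nx = self.values.shape
        vals = np.where(np.isnan(self.values), nodata, self.values)
        header = (f"ncols {nx}\nnrows {ny}\nxllcorner {self.xmin}\n"
                  f"yllcorner {self.ymax - ny * self.cell_size}\n"
                  f"cellsize {self.cell_size}\nNODATA_value {nodata}\n")
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, vals, fmt="%.10g")

    @classmethod
    def from_ascii(cls, path) -> "RasterGrid":
        meta = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                meta[key.lower()] = float(val)
            vals = np.loadtxt(fh)
        vals = np.atleast_2d(vals)
        nodata = meta.get("nodata_value")
        if nodata is not None:
            vals = np.where(vals == nodata, np.nan, vals)
        ymax = meta["yllcorner"] + meta["nrows"] * meta["cellsize"]
        return cls(vals, xmin=meta["xllcorner"], ymax=ymax, cell_size=meta["cellsize"])


@dataclass
class SuitabilityThresholds:
    """Index range considered suitable (inclusive), with its percentile levels."""

    low: float
    high: float
    percentile_low: float = 5.0
    percentile_high: float = 95.0

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValueError("low must be <= high")
        if not (0 <= self.percentile_low < self.percentile_high <= 100):
            raise ValueError("require 0 <= percentile_low < percentile_high <= 100")


@dataclass
class BinaryMask:
    """Suitable/unsuitable flags aligned to a raster grid."""

    values: np.ndarray
    xmin: float
    ymax: float
    cell_size: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("mask must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")

    @property
    def area(self) -> float:
        """Suitable area in m^2 = count of suitable cells x cell area."""
        return float(self.values.sum()) * self.cell_size ** 2

    def aligned_with(self, other) -> bool:
        return RasterGrid.aligned_with(self, other)  # same geometry fields

    def as_raster(self) -> RasterGrid:
        return RasterGrid(self.values.astype(float), self.xmin, self.ymax, self.cell_size)


def extract_at_points(raster: RasterGrid, points: PointSet) -> np.ndarray:
    """Value of the raster cell containing each point; NaN outside the extent
    or on nodata cells (with a warning for out-of-extent points)."""
    row, col = raster.cell_of(points.x, points.y)
    ny, nx = raster.values.shape
    inside = (row >= 0) & (row < ny) & (col >= 0) & (col < nx)
    if not inside.all():
        warnings.warn(f"{int((~inside).sum())} point(s) outside raster extent -> missing",
                      stacklevel=2)
    out = np.full(len(points), np.nan)
    out[inside] = raster.values[row[inside], col[inside]]
    return out


def mean_over_dates(value_vectors) -> np.ndarray:
    """Element-wise mean over per-date extraction vectors, skipping missing
    values; positions missing on every date stay missing."""
    vecs = [np.asarray(v, dtype=float) for v in value_vectors]
    if not vecs:
        raise ValueError("need at least one vector")
    lengths = {v.shape[0] for v in vecs}
    if len(lengths) != 1:
        raise ValueError("vectors must share one length")
    stack = np.vstack(vecs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return np.nanmean(stack, axis=0)


def percentile_thresholds(values, p_low: float = 5.0, p_high: float = 95.0) -> SuitabilityThresholds:
    """Suitability range from the pooled per-nest index values.

    Percentiles use linear interpolation between order statistics
    (Hyndman-Fan type 7), recorded in the result for provenance.
    """
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size < 2:
        raise ValueError("need at least 2 non-missing values for percentiles")
    low, high = np.percentile(vals, [p_low, p_high], method="linear")
    return SuitabilityThresholds(float(low), float(high), p_low, p_high)


def threshold_mask(raster: RasterGrid, thresholds: SuitabilityThresholds) -> BinaryMask:
    """Suitable iff low <= value <= high (inclusive); nodata is unsuitable."""
    with np.errstate(invalid="ignore"):
        ok = (raster.values >= thresholds.low) & (raster.values <= thresholds.high)
    ok &= np.isfinite(raster.values)
    return BinaryMask(ok, raster.xmin, raster.ymax, raster.cell_size)


def overlap_fraction(a: BinaryMask, b: BinaryMask, mode: str = "min") -> float:
    """Between-mask agreement in [0, 1].

    ``mode="min"``: intersection area / min(area a, area b) — 1 exactly when
    the smaller mask is contained in the larger. ``mode="jaccard"``:
    intersection / union.
    """
    if not a.aligned_with(b):
        raise ValueError("masks are not grid-aligned")
    if a.area == 0 or b.area == 0:
        raise ValueError("overlap undefined for an empty mask")
    inter = float(np.sum(a.values & b.values))
    if mode == "min":
        denom = min(a.values.sum(), b.values.sum())
    elif mode == "jaccard":
        denom = float(np.sum(a.values | b.values))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return inter / denom


def combine_masks(masks, mode: str = "union") -> BinaryMask:
    """Cell-wise OR (union) or AND (intersection) of aligned masks."""
    masks = list(masks)
    if not masks:
        raise ValueError("need at least one mask")
    first = masks[0]
    for m in masks[1:]:
        if not first.aligned_with(m):
            raise ValueError("masks are not grid-aligned")
    stack = np.stack([m.values for m in masks])
    if mode == "union":
        vals = stack.any(axis=0)
    elif mode == "intersection":
        vals = stack.all(axis=0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return BinaryMask(vals, first.xmin, first.ymax, first.cell_size)


def mask_to_region(mask: BinaryMask) -> Polygon | MultiPolygon:
    """Union of the suitable cells' squares as a polygon; area-conserving."""
    rows, cols = np.nonzero(mask.values)
    if rows.size == 0:
        raise ValueError("mask has no suitable cell")
    cs = mask.cell_size
    x0 = mask.xmin + cols * cs
    y1 = mask.ymax - rows * cs
    boxes = shapely.box(x0, y1 - cs, x0 + cs, y1)
    region = shapely.union_all(boxes)
    if abs(region.area - mask.area) > 1e-6 * max(mask.area, 1.0):
        raise AssertionError("mask/region area mismatch")
    return region


def mean_raster(rasters) -> RasterGrid:
    """Cell-wise mean of aligned rasters, skipping nodata."""
    rasters = list(rasters)
    if not rasters:
        raise ValueError("need at least one raster")
    first = rasters[0]
    for r in rasters[1:]:
        if not first.aligned_with(r):
            raise ValueError("rasters are not grid-aligned")
    stack = np.stack([r.values for r in rasters])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        vals = np.nanmean(stack, axis=0)
    return RasterGrid(vals, first.xmin, first.ymax, first.cell_size)


def suitable_region_from_rasters(rasters_by_index: dict, nests_by_year: dict,
                                 p_low: float = 5.0, p_high: float = 95.0,
                                 overlap_mode: str = "min"):
    """Full mask pipeline: per-nest extraction -> yearly means -> pooled
    percentiles -> yearly masks -> across-year mean raster -> per-index mask
    -> union across indices.

    Parameters
    ----------
    rasters_by_index
        ``{index_name: {year: [RasterGrid per date, ...]}}``.
    nests_by_year
        ``{year: PointSet}`` of observed nests.

    Returns
    -------
    (region, info)
        The final suitable region polygon and a dict with per-index
        thresholds, yearly mask areas, pairwise overlap fractions (both
        conventions) and the final area.
    """
    index_masks = []
    info: dict = {"indices": {}, "percentile_low": p_low, "percentile_high": p_high,
                  "percentile_method": "linear (type 7)"}
    for index_name, by_year in rasters_by_index.items():
        pooled = []
        for year, date_rasters in by_year.items():
            if year not in nests_by_year:
                continue
            pts = nests_by_year[year]
            per_date = [extract_at_points(r, pts) for r in date_rasters]
            pooled.append(mean_over_dates(per_date))
        thresholds = percentile_thresholds(np.concatenate(pooled), p_low, p_high)
        yearly_masks = {}
        for year, date_rasters in by_year.items():
            yearly_masks[year] = threshold_mask(mean_raster(date_rasters), thresholds)
        years = list(yearly_masks)
        overlaps = {}
        for i, yi in enumerate(years):
            for yj in years[i + 1:]:
                overlaps[f"{yi}-{yj}"] = {
                    "min": overlap_fraction(yearly_masks[yi], yearly_masks[yj], "min"),
                    "jaccard": overlap_fraction(yearly_masks[yi], yearly_masks[yj], "jaccard"),
                }
        # across-year mean of the per-year mean rasters, then the same range
        index_mask = threshold_mask(mean_raster([mean_raster(by_year[y]) for y in years]),
                                    thresholds)
        index_masks.append(index_mask)
        info["indices"][index_name] = {
            "thresholds": (thresholds.low, thresholds.high),
            "yearly_area_m2": {str(y): yearly_masks[y].area for y in years},
            "overlap": overlaps,
            "min_overlap": (min(v[overlap_mode] for v in overlaps.values())
                            if overlaps else None),
            "index_area_m2": index_mask.area,
        }
    final_mask = combine_masks(index_masks, "union")
    region = mask_to_region(final_mask)
    info["final_area_m2"] = final_mask.area
    return region, info
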