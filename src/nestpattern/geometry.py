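"""Planar geometry primitives shared by every analysis stage.

All coordinates are planar metres in a single projected CRS. The package
never reprojects: nests, leks, polylines and polygons must already share
one CRS. Geodesic (lat/lon) distances are out of scope.

Point sets are thin wrappers around ``(n, 2)`` float arrays; polylines and
polygons are shapely ``LineString`` / ``Polygon`` / ``MultiPolygon``
geometries validated by :func:`ensure_polyline` / :func:`ensure_region`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.spatial import cKDTree
from shapely.geometry import LineString, MultiPolygon, Polygon

__all__ = [
    "PointSet",
    "SpatialFeatureSet",
    "nearest_neighbor_distances",
    "min_distances_to_points",
    "distance_to_polyline",
    "distances_to_polyline",
    "contains",
    "contains_xy",
    "ensure_polyline",
    "ensure_region",
]


@dataclass
class PointSet:
    """An ordered collection of planar points (metres) with a free-text label.

    Parameters
    ----------
    coords
        Array-like of shape ``(n, 2)``: easting/northing in metres.
    label
        Free text, typically the year of a nest distribution.
    """

    coords: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.coords, dtype=float)
        if arr.size == 0:
            arr = arr.reshape(0, 2)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError(f"coords must have shape (n, 2); got {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("coordinates must be finite")
        self.coords = arr

    @classmethod
    def from_xy(cls, x, y, label: str = "") -> "PointSet":
        return cls(np.column_stack([np.asarray(x, float), np.asarray(y, float)]), label)

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def x(self) -> np.ndarray:
        return self.coords[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.coords[:, 1]


def _as_coords(points) -> np.ndarray:
    if isinstance(points, PointSet):
        return points.coords
    arr = np.asarray(points, dtype=float)
    if arr.ndim == 1:
        arr = arr.reshape(1, 2)
    return arr


def nearest_neighbor_distances(points) -> np.ndarray:
    """First-degree nearest-neighbour distance for every point in the set.

    Element ``i`` is ``min_{j != i} ||p_i - p_j||``. Coincident points are
    allowed and yield distance 0 (with a warning); fewer than two points
    leave the nearest neighbour undefined and raise ``ValueError``.
    """
    coords = _as_coords(points)
    n = coords.shape[0]
    if n < 2:
        raise ValueError("nearest-neighbour distance requires at least 2 points")
    tree = cKDTree(coords)
    dist, _ = tree.query(coords, k=2)
    out = dist[:, 1]
    if np.any(out == 0.0):
        warnings.warn("duplicate points present: nearest-neighbour distance 0", stacklevel=2)
    return out


def min_distances_to_points(points, targets) -> np.ndarray:
    """Distance from each point to its nearest target point (metres)."""
    coords = _as_coords(points)
    tcoords = _as_coords(targets)
    if tcoords.shape[0] == 0:
        raise ValueError("targets must be nonempty")
    tree = cKDTree(tcoords)
    dist, _ = tree.query(coords, k=1)
    return np.atleast_1d(dist)


def ensure_polyline(line) -> LineString:
    """Validate/coerce a polyline: >= 2 vertices, no repeated consecutive vertex."""
    if not isinstance(line, LineString):
        line = LineString(np.asarray(line, dtype=float))
    coords = np.asarray(line.coords, dtype=float)
    if coords.shape[0] < 2:
        raise ValueError("polyline needs at least 2 vertices")
    if not np.all(np.isfinite(coords)):
        raise ValueError("polyline vertices must be finite")
    if np.any(np.all(np.diff(coords, axis=0) == 0.0, axis=1)):
        raise ValueError("polyline has identical consecutive vertices")
    return line


def ensure_region(region) -> Polygon | MultiPolygon:
    """Validate a polygonal region: positive area, well-defined membership."""
    if not isinstance(region, (Polygon, MultiPolygon)):
        region = Polygon(np.asarray(region, dtype=float))
    if region.is_empty or region.area <= 0:
        raise ValueError("region must have positive area")
    if not region.is_valid:
        region = shapely.make_valid(region)
    return region


def distances_to_polyline(points, line: LineString) -> np.ndarray:
    """Shortest distance from each point to the polyline (metres).

    The minimum over segments of the point-to-segment distance: the
    perpendicular foot when it falls within the segment, else the nearer
    endpoint. Delegated to shapely's exact segment distance.
    """
    line = ensure_polyline(line)
    coords = _as_coords(points)
    return shapely.distance(shapely.points(coords), line)


def distance_to_polyline(point, line: LineString) -> float:
    """Scalar convenience wrapper of :func:`distances_to_polyline`."""
    return float(distances_to_polyline(point, line)[0])


def contains_xy(region, x, y) -> np.ndarray:
    """Vectorised boundary-inclusive point-in-region test."""
    region = ensure_region(region)
    # for points, intersects == closure membership: boundary counts as inside
    return shapely.intersects_xy(region, np.asarray(x, float), np.asarray(y, float))


def contains(region, point) -> bool:
    """Boundary-inclusive membership of a single point in a polygonal region."""
    coords = _as_coords(point)
    return bool(contains_xy(region, coords[0, 0], coords[0, 1]))


@dataclass
class SpatialFeatureSet:
    """The landscape features a nest distribution is tested against.

    Attributes
    ----------
    region
        Suitable breeding area (Polygon/MultiPolygon, m^2).
    shore, edge
        Shoreline and meadow-edge polylines.
    lek_coords
        ``(k, 2)`` lek centre coordinates.
    lek_active_years
        One set of year labels per lek; a lek contributes to a year's test
        only when active that year.
    lek_ids
        Optional identifiers, defaults to ``lek0..lek{k-1}``.
    """

    region: Polygon | MultiPolygon
    shore: LineString
    edge: LineString
    lek_coords: np.ndarray
    lek_active_years: list
    lek_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.region = ensure_region(self.region)
        self.shore = ensure_polyline(self.shore)
        self.edge = ensure_polyline(self.edge)
        self.lek_coords = np.asarray(self.lek_coords, dtype=float).reshape(-1, 2)
        self.lek_active_years = [frozenset(s) for s in self.lek_active_years]
        if len(self.lek_active_years) != self.lek_coords.shape[0]:
            raise ValueError("one active-year set required per lek")
        if not self.lek_ids:
            self.lek_ids = [f"lek{i}" for i in range(self.lek_coords.shape[0])]

    @property
    def n_leks(self) -> int:
        return self.lek_coords.shape[0]

    def leks_active_in(self, year) -> PointSet:
        """Centres of the leks active in ``year``."""
        mask = np.array([year in s for s in self.lek_active_years], dtype=bool)
        if not mask.any():
            raise ValueError(f"no lek active in year {year!r}")
        return PointSet(self.lek_coords[mask], label=f"leks:{year}")
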