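"""Planar trajectory geometry and the intersections-per-kilometre index.

Coordinate conventions
----------------------
All positions live in a local tangent plane centred on the radar station:
``x`` metres east, ``y`` metres north.  Radar fixes arrive as compass polar
coordinates (bearing clockwise from north, range in metres) and are projected
with ``x = range * sin(bearing)``, ``y = range * cos(bearing)``.  At the scene
scale of a few kilometres, Earth curvature is far below measurement
resolution and is ignored.

A trajectory is the two-segment polyline through its start-, mid- and
end-point fixes.  The avoidance statistic divides the number of trajectories
that touch the wind-farm polygon (closed-region semantics: crossing,
touching the boundary, or lying inside all count) by the summed trajectory
length in kilometres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import shapely
from shapely.geometry import LineString, MultiPoint, Point, Polygon

__all__ = [
    "PolarFix",
    "PlanarPoint",
    "Trajectory",
    "TrajectorySet",
    "FarmPolygon",
    "DetectionDisk",
    "polar_to_planar",
    "planar_to_polar",
    "trajectory_length_km",
    "build_farm_polygon",
    "trajectory_intersects",
    "count_intersections",
    "count_crossing_events",
    "intersections_per_km",
    "index_from_counts",
    "intersection_mask",
]

DEFAULT_DETECTION_RADIUS_M = 6000.0


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


@dataclass(frozen=True)
class PolarFix:
    """One radar observation: compass bearing (degrees CW from north) + range (m)."""

    bearing_deg: float
    range_m: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.bearing_deg) or not math.isfinite(self.range_m):
            raise ValidationError(f"non-finite polar fix {self!r}")
        if self.range_m <= 0:
            raise ValidationError(
                f"range must be strictly positive, got {self.range_m} m in {self!r}"
            )
        b = self.bearing_deg % 360.0
        object.__setattr__(self, "bearing_deg", 0.0 if b >= 360.0 else b)


@dataclass(frozen=True)
class PlanarPoint:
    """Point in the radar-centred frame: x metres east, y metres north."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValidationError(f"non-finite planar point ({self.x}, {self.y})")

    def distance_to(self, other: "PlanarPoint") -> float:
        return math.hypot(self.x - other.x, self.y - other.y)

    def as_tuple(self) -> tuple[float, float]:
        return (self.x, self.y)


def polar_to_planar(fix: PolarFix) -> PlanarPoint:
    """Project a compass polar fix onto the local east/north plane."""
    theta = math.radians(fix.bearing_deg)
    return PlanarPoint(fix.range_m * math.sin(theta), fix.range_m * math.cos(theta))


def planar_to_polar(p: PlanarPoint) -> PolarFix:
    """Inverse projection; bearing measured clockwise from north."""
    rng = math.hypot(p.x, p.y)
    if rng <= 0:
        raise ValidationError("cannot recover a bearing for the origin")
    return PolarFix(math.degrees(math.atan2(p.x, p.y)) % 360.0, rng)


@dataclass(frozen=True)
class Trajectory:
    """Two-segment polyline through start, mid and end fixes.

    Degenerate trajectories (all three points coincident, zero length) are
    valid objects — they are flagged via :attr:`is_degenerate` and reported
    by consumers rather than silently dropped.
    """

    id: str
    start: PlanarPoint
    mid: PlanarPoint
    end: PlanarPoint
    season: str = "other"

    @property
    def points(self) -> tuple[PlanarPoint, PlanarPoint, PlanarPoint]:
        return (self.start, self.mid, self.end)

    @property
    def length_m(self) -> float:
        return self.start.distance_to(self.mid) + self.mid.distance_to(self.end)

    @property
    def is_degenerate(self) -> bool:
        return self.length_m == 0.0

    def coords(self) -> np.ndarray:
        """(3, 2) array of the start/mid/end coordinates."""
        return np.array([p.as_tuple() for p in self.points], dtype=float)


def trajectory_length_km(t: Trajectory) -> float:
    """Polyline length start→mid→end, in kilometres."""
    return t.length_m / 1000.0


@dataclass
class TrajectorySet:
    """Ordered collection of trajectories sharing a season label."""

    trajectories: list[Trajectory]
    season: str = "other"

    def __post_init__(self) -> None:
        ids = [t.id for t in self.trajectories]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate trajectory ids: {dupes}")

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self) -> Iterator[Trajectory]:
        return iter(self.trajectories)

    @property
    def total_length_km(self) -> float:
        return sum(trajectory_length_km(t) for t in self.trajectories)

    @property
    def degenerate_ids(self) -> list[str]:
        return [t.id for t in self.trajectories if t.is_degenerate]

    def coords(self) -> np.ndarray:
        """(n, 3, 2) coordinate array for vectorized geometry."""
        if not self.trajectories:
            return np.empty((0, 3, 2))
        return np.stack([t.coords() for t in self.trajectories])


@dataclass(frozen=True)
class DetectionDisk:
    """Circular radar coverage region; default radius 6 km."""

    radius_m: float = DEFAULT_DETECTION_RADIUS_M
    center: PlanarPoint = field(default_factory=lambda: PlanarPoint(0.0, 0.0))

    def __post_init__(self) -> None:
        if self.radius_m <= 0:
            raise ValidationError(f"detection radius must be positive, got {self.radius_m}")

    def contains(self, p: PlanarPoint, tol: float = 1e-9) -> bool:
        return self.center.distance_to(p) <= self.radius_m * (1 + tol)


class FarmPolygon:
    """Closed simple polygon bounding the turbine array (the avoidance target).

    Wraps a shapely polygon; construction validates simplicity and positive
    area.  Closed-region semantics: a trajectory touching the boundary or
    contained in the interior intersects the farm.
    """

    def __init__(self, vertices: Sequence[PlanarPoint] | Sequence[tuple[float, float]]):
        ring = [
            v.as_tuple() if isinstance(v, PlanarPoint) else (float(v[0]), float(v[1]))
            for v in vertices
        ]
        if len(ring) < 3:
            raise ValidationError("a farm polygon needs at least 3 vertices")
        poly = Polygon(ring)
        if not poly.is_valid or poly.area <= 0:
            raise ValidationError("farm polygon must be simple with positive area")
        self._poly = poly
        shapely.prepare(self._poly)

    @property
    def shapely(self) -> Polygon:
        return self._poly

    @property
    def area_km2(self) -> float:
        return self._poly.area / 1e6

    @property
    def vertices(self) -> list[PlanarPoint]:
        return [PlanarPoint(x, y) for x, y in self._poly.exterior.coords]

    @property
    def centroid(self) -> PlanarPoint:
        c = self._poly.centroid
        return PlanarPoint(c.x, c.y)

    def __repr__(self) -> str:
        return f"FarmPolygon(n_vertices={len(self._poly.exterior.coords) - 1}, area={self.area_km2:.3f} km2)"


def build_farm_polygon(
    turbines: Iterable[PlanarPoint] | np.ndarray,
) -> FarmPolygon:
    """Convex hull of the turbine positions as the farm perimeter.

    The perimeter ring of a real farm is rarely published; the hull is the
    canonical closed simple ring containing every turbine.  A user-supplied
    explicit ring can be passed to :class:`FarmPolygon` directly instead.
    """
    if isinstance(turbines, np.ndarray):
        turbines = [tuple(row) for row in turbines.reshape(-1, 2)]
    pts = [
        p.as_tuple() if isinstance(p, PlanarPoint) else (float(p[0]), float(p[1]))
        for p in turbines
    ]
    if len(pts) < 3:
        raise ValidationError("cannot form a farm polygon from fewer than 3 turbines")
    hull = MultiPoint(pts).convex_hull
    if hull.geom_type != "Polygon":
        raise ValidationError("turbine positions are collinear; no polygon can be formed")
    return FarmPolygon(list(hull.exterior.coords)[:-1])


def _as_geometry(t: Trajectory):
    if t.is_degenerate:
        return Point(t.start.as_tuple())
    return LineString([p.as_tuple() for p in t.points])


def trajectory_intersects(t: Trajectory, poly: FarmPolygon) -> bool:
    """True iff the polyline shares at least one point with the closed farm region."""
    return bool(shapely.intersects(_as_geometry(t), poly.shapely))


def intersection_mask(coords: np.ndarray, poly: FarmPolygon) -> np.ndarray:
    """Vectorized intersection test for an (n, 3, 2) coordinate array.

    Degenerate rows (all points coincident) are tested as points, matching
    :func:`trajectory_intersects`.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.size == 0:
        return np.zeros(0, dtype=bool)
    degen = np.all(coords == coords[:, :1, :], axis=(1, 2))
    out = np.zeros(len(coords), dtype=bool)
    if np.any(~degen):
        lines = shapely.linestrings(coords[~degen])
        out[~degen] = shapely.intersects(lines, poly.shapely)
    if np.any(degen):
        pts = shapely.points(coords[degen, 0, :])
        out[degen] = shapely.intersects(pts, poly.shapely)
    return out


def count_intersections(ts: TrajectorySet, poly: FarmPolygon) -> int:
    """Number of trajectories intersecting the farm; each counts at most once."""
    return int(intersection_mask(ts.coords(), poly).sum())


def count_crossing_events(ts: TrajectorySet, poly: FarmPolygon) -> int:
    """Per-crossing sensitivity count: separate entries into the farm region.

    Each maximal connected piece of a trajectory lying within the closed
    polygon counts as one event, so a path that enters, leaves and re-enters
    contributes 2.  The default statistic is the per-trajectory binary count.
    """
    total = 0
    for t in ts:
        inter = _as_geometry(t).intersection(poly.shapely)
        if inter.is_empty:
            continue
        total += len(inter.geoms) if hasattr(inter, "geoms") else 1
    return total


def index_from_counts(n_intersections: int, total_length_km: float) -> float:
    """The avoidance index: intersections divided by summed length in km."""
    if total_length_km <= 0:
        raise ValidationError("index undefined: total trajectory length is zero")
    return n_intersections / total_length_km


def intersections_per_km(
    ts: TrajectorySet, poly: FarmPolygon, *, per_crossing: bool = False
) -> float:
    """Observed avoidance index for a trajectory set against a farm polygon."""
    count = count_crossing_events(ts, poly) if per_crossing else count_intersections(ts, poly)
    return index_from_counts(count, ts.total_length_km)
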