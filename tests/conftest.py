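"""Shared fixtures and independent brute-force geometry oracles.

The oracles deliberately avoid shapely: point-in-polygon is an even–odd
ray-casting test and segment–polygon intersection is dense sampling along
the segment at 0.1 m spacing, so they can arbitrate the vectorized
implementation on small random scenes.
"""

from __future__ import annotations

import numpy as np
import pytest

from windtraj.geometry import (
    DetectionDisk,
    FarmPolygon,
    PlanarPoint,
    Trajectory,
    TrajectorySet,
    build_farm_polygon,
)
from windtraj.synthetic import LayoutConfig, generate_layout


def point_in_polygon_oracle(x: float, y: float, ring: np.ndarray) -> bool:
    """Even–odd ray casting against an open ring of (n, 2) vertices."""
    inside = False
    n = len(ring)
    for i in range(n):
        x1, y1 = ring[i]
        x2, y2 = ring[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            x_cross = x1 + (y - y1) / (y2 - y1) * (x2 - x1)
            if x < x_cross:
                inside = not inside
    return inside


def points_in_polygon_oracle(pts: np.ndarray, ring: np.ndarray) -> np.ndarray:
    """Vectorized even–odd test for (m, 2) points against an open ring."""
    x, y = pts[:, 0], pts[:, 1]
    inside = np.zeros(len(pts), dtype=bool)
    n = len(ring)
    for i in range(n):
        x1, y1 = ring[i]
        x2, y2 = ring[(i + 1) % n]
        crosses = (y1 > y) != (y2 > y)
        with np.errstate(divide="ignore", invalid="ignore"):
            x_cross = x1 + (y - y1) / (y2 - y1) * (x2 - x1)
        inside ^= crosses & (x < x_cross)
    return inside


def trajectory_intersects_oracle(
    t: Trajectory, ring: np.ndarray, spacing: float = 0.1
) -> bool:
    """Dense-sampling oracle: any sample point along either segment inside?"""
    for a, b in ((t.start, t.mid), (t.mid, t.end)):
        length = a.distance_to(b)
        n = max(2, int(np.ceil(length / spacing)) + 1)
        s = np.linspace(0.0, 1.0, n)
        pts = np.column_stack((a.x + s * (b.x - a.x), a.y + s * (b.y - a.y)))
        if points_in_polygon_oracle(pts, ring).any():
            return True
    return False


def make_trajectory(tid, start, mid, end, season="other") -> Trajectory:
    return Trajectory(
        id=str(tid),
        start=PlanarPoint(*start),
        mid=PlanarPoint(*mid),
        end=PlanarPoint(*end),
        season=season,
    )


@pytest.fixture(scope="session")
def disk() -> DetectionDisk:
    return DetectionDisk()


@pytest.fixture(scope="session")
def unit_square_km() -> FarmPolygon:
    """1 km × 1 km square with corners (0,0)…(1000,1000)."""
    return FarmPolygon([(0, 0), (1000, 0), (1000, 1000), (0, 1000)])


@pytest.fixture(scope="session")
def default_layout() -> list[PlanarPoint]:
    return generate_layout(LayoutConfig())


@pytest.fixture(scope="session")
def default_farm(default_layout) -> FarmPolygon:
    return build_farm_polygon(default_layout)


@pytest.fixture()
def toy_set(unit_square_km) -> TrajectorySet:
    """Five trajectories, exactly two of which touch the unit square farm."""
    return TrajectorySet(
        [
            make_trajectory(1, (-500, 500), (500, 500), (1500, 500)),  # crosses
            make_trajectory(2, (500, -500), (500, 500), (500, 1500)),  # crosses
            make_trajectory(3, (2000, 2000), (2500, 2500), (3000, 3000)),  # away
            make_trajectory(4, (-2000, -100), (0, -200), (2000, -100)),  # below
            make_trajectory(5, (-100, 1200), (500, 1100), (1200, 1200)),  # above
        ]
    )
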