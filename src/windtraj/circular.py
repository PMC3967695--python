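"""Circular summaries of flight bearings: mean direction and resultant length.

Bearings are compass angles — degrees clockwise from north — so the unit
vector of bearing θ is (sin θ, cos θ) in the east/north plane.  The mean
resultant length r measures directional concentration (1 = all bearings
identical, 0 = no preferred direction); the mean direction μ is undefined
when r = 0 and is flagged rather than reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .geometry import Trajectory, ValidationError

__all__ = ["CircularSummary", "trajectory_bearing", "circular_summary"]

# Below this resultant length the mean direction is numerically meaningless.
_R_UNDEFINED_TOL = 1e-12


@dataclass(frozen=True)
class CircularSummary:
    """Mean direction (deg CW from north), mean resultant length, sample size."""

    mu_deg: float
    r: float
    n: int
    mu_defined: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.r <= 1.0 + 1e-12):
            raise ValidationError(f"resultant length out of [0, 1]: {self.r}")


def trajectory_bearing(t: Trajectory, *, segment_weighted: bool = False) -> float:
    """Flight bearing of one trajectory, degrees clockwise from north.

    Default: the bearing of the straight start→end displacement, ignoring
    the mid-point.  With ``segment_weighted=True`` the two segment directions
    are averaged with equal weight instead (a sensitivity alternative; note
    that weighting segments by their *length* recovers the displacement
    bearing exactly, so the equal-weight mean is the only distinct variant).
    """
    if segment_weighted:
        dx = dy = 0.0
        for a, b in ((t.start, t.mid), (t.mid, t.end)):
            sx, sy = b.x - a.x, b.y - a.y
            norm = math.hypot(sx, sy)
            if norm > 0:
                dx += sx / norm
                dy += sy / norm
    else:
        dx, dy = t.end.x - t.start.x, t.end.y - t.start.y
    if dx == 0 and dy == 0:
        raise ValidationError(f"undefined bearing: trajectory {t.id!r} has start == end")
    b = math.degrees(math.atan2(dx, dy)) % 360.0
    return 0.0 if b >= 360.0 else b


def circular_summary(bearings_deg: Iterable[float]) -> CircularSummary:
    """Unweighted circular mean of compass bearings.

    With S and C the means of sin and cos of the bearings, r = sqrt(S²+C²)
    and μ = atan2(S, C) mapped to [0, 360).  Every bearing contributes
    equally, as in a plain list-of-angles summary.
    """
    theta = np.radians(np.asarray(list(bearings_deg), dtype=float))
    if theta.size == 0:
        raise ValidationError("circular summary of an empty bearing list")
    s = float(np.mean(np.sin(theta)))
    c = float(np.mean(np.cos(theta)))
    r = min(math.hypot(s, c), 1.0)
    if r < _R_UNDEFINED_TOL:
        return CircularSummary(mu_deg=float("nan"), r=r, n=theta.size, mu_defined=False)
    mu = math.degrees(math.atan2(s, c)) % 360.0
    if mu >= 360.0:  # (-eps) % 360 rounds to 360.0
        mu = 0.0
    return CircularSummary(mu_deg=mu, r=r, n=theta.size, mu_defined=True)
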