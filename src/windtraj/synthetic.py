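"""Synthetic radar-like trajectory sets and turbine layouts.

The generator emulates the statistical structure a ridge-guided soaring
migration produces on a marine radar: flight bearings concentrated around a
seasonal mean direction (von Mises), start points clustered in a sector of
the detection disk (a ridgeline to the northwest), lognormal leg lengths,
and an optional avoidance behaviour that deflects trajectories around the
wind-farm polygon.  It makes no behavioural claim — deflection is a minimal
rotate-until-clear mechanism that manufactures an avoidance signal for
pipeline and test use.

The turbine layout places a configurable number of turbines on west–east
rows; default 98 turbines on 4 rows whose convex-hull footprint is
9.49 km², matching the scale of a mid-size coastal-plain wind farm.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import shapely
from scipy.optimize import brentq
from scipy.special import i0e, i1e

from .geometry import (
    DetectionDisk,
    FarmPolygon,
    PlanarPoint,
    PolarFix,
    Trajectory,
    TrajectorySet,
    ValidationError,
    polar_to_planar,
)
from .nullmodels import _sample_disk

__all__ = [
    "LayoutConfig",
    "SyntheticConfig",
    "generate_layout",
    "generate_trajectories",
    "generate_model1_set",
    "kappa_for_resultant",
    "resultant_for_kappa",
    "SEASON_PROFILES",
]

logger = logging.getLogger(__name__)

# Target mean resultant lengths of the two seasonal profiles: a tightly
# clustered southbound fall passage vs. widely scattered spring movement.
SEASON_PROFILES: dict[str, dict[str, float]] = {
    "fall_like": {"target_r": 0.91, "mean_bearing_deg": 143.9},
    "spring_like": {"target_r": 0.42, "mean_bearing_deg": 184.8},
}


def resultant_for_kappa(kappa: float) -> float:
    """Population mean resultant length A(κ) = I₁(κ)/I₀(κ) of a von Mises law."""
    if kappa < 0:
        raise ValidationError("concentration must be nonnegative")
    if kappa == 0:
        return 0.0
    return float(i1e(kappa) / i0e(kappa))


def kappa_for_resultant(r: float) -> float:
    """Invert A(κ) = r numerically (r in [0, 1))."""
    if not (0.0 <= r < 1.0):
        raise ValidationError(f"target resultant length must be in [0, 1), got {r}")
    if r == 0.0:
        return 0.0
    return float(brentq(lambda k: resultant_for_kappa(k) - r, 1e-9, 1e4))


@dataclass
class LayoutConfig:
    """West–east row layout of turbines.

    The row x-extent is fixed and the row spacing is derived from the target
    hull footprint, so the convex hull of the default layout is a
    ``width × height`` rectangle of exactly ``target_area_km2``
    (height = area / width; every row spans the full width).
    """

    n_turbines: int = 98
    n_rows: int = 4
    width_m: float = 4800.0
    target_area_km2: float = 9.49
    center: PlanarPoint = field(default_factory=lambda: PlanarPoint(0.0, 0.0))
    seed: int = 0
    x_jitter_m: float = 0.0  # optional along-row jitter; rows stay on their lines

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_turbines < self.n_rows:
            raise ValidationError(
                f"cannot place {self.n_turbines} turbines on {self.n_rows} rows "
                "(every row needs at least one turbine)"
            )
        if self.width_m <= 0 or self.target_area_km2 <= 0:
            raise ValidationError("layout width and target area must be positive")

    @property
    def height_m(self) -> float:
        return self.target_area_km2 * 1e6 / self.width_m

    def row_counts(self) -> list[int]:
        base, extra = divmod(self.n_turbines, self.n_rows)
        return [base + (1 if i < extra else 0) for i in range(self.n_rows)]


def generate_layout(cfg: LayoutConfig) -> list[PlanarPoint]:
    """Turbine positions on ``n_rows`` west–east lines; deterministic given seed."""
    rng = np.random.default_rng(cfg.seed)
    x0 = cfg.center.x - cfg.width_m / 2.0
    y0 = cfg.center.y - cfg.height_m / 2.0
    row_gap = cfg.height_m / (cfg.n_rows - 1) if cfg.n_rows > 1 else 0.0
    points: list[PlanarPoint] = []
    for i, count in enumerate(cfg.row_counts()):
        y = y0 + i * row_gap if cfg.n_rows > 1 else cfg.center.y
        if count == 1:
            xs = np.array([cfg.center.x])
        else:
            xs = x0 + np.arange(count) * (cfg.width_m / (count - 1))
        if cfg.x_jitter_m > 0:
            # jitter interior turbines only, keeping the hull footprint exact
            jit = rng.uniform(-cfg.x_jitter_m, cfg.x_jitter_m, count)
            jit[[0, -1]] = 0.0
            xs = xs + jit
        points.extend(PlanarPoint(float(x), float(y)) for x in xs)
    return points


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic trajectory generator.

    ``season_profile`` sets the von Mises concentration of flight headings
    (``fall_like``: tightly clustered, target r = 0.91; ``spring_like``:
    scattered, target r = 0.42) and the default mean bearing.  Start points
    are drawn in ``start_sector`` — (bearing_lo, bearing_hi, range_lo,
    range_hi) in compass degrees and metres — defaulting to a northwest
    sector that emulates departure from a ridgeline.  Leg lengths are
    lognormal.  With ``avoidance="deflect"`` any trajectory that would cross
    the farm polygon (buffered by ``deflect_buffer_m``) is rotated about its
    start point, in 5° steps, by the minimal angle that clears the buffer.
    """

    n_trajectories: int = 193
    season_profile: Literal["fall_like", "spring_like"] = "fall_like"
    mean_bearing_deg: float | None = None
    kappa: float | None = None
    start_sector: tuple[float, float, float, float] = (280.0, 350.0, 3500.0, 5800.0)
    leg_length_log_mean: float = math.log(3200.0)
    leg_length_log_sigma: float = 0.35
    leg_bearing_kappa: float = 60.0
    mid_jitter_m: float = 120.0
    avoidance: Literal["none", "deflect"] = "none"
    deflect_buffer_m: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trajectories < 1:
            raise ValidationError("need at least one trajectory")
        if self.season_profile not in SEASON_PROFILES:
            raise ValidationError(f"unknown season profile {self.season_profile!r}")
        if self.kappa is not None and self.kappa < 0:
            raise ValidationError("concentration must be nonnegative")
        if self.deflect_buffer_m < 0:
            raise ValidationError("deflection buffer must be nonnegative")
        lo, hi, rlo, rhi = self.start_sector
        if not (0 < rlo <= rhi):
            raise ValidationError("start sector range band must satisfy 0 < lo <= hi")

    @property
    def effective_kappa(self) -> float:
        if self.kappa is not None:
            return self.kappa
        return kappa_for_resultant(SEASON_PROFILES[self.season_profile]["target_r"])

    @property
    def effective_mean_bearing(self) -> float:
        if self.mean_bearing_deg is not None:
            return self.mean_bearing_deg
        return SEASON_PROFILES[self.season_profile]["mean_bearing_deg"]

    @property
    def season(self) -> str:
        return "fall" if self.season_profile == "fall_like" else "spring"


def _unit(bearing_rad: float) -> np.ndarray:
    """East/north unit vector of a compass bearing in radians."""
    return np.array([math.sin(bearing_rad), math.cos(bearing_rad)])


def _sample_start(cfg: SyntheticConfig, disk: DetectionDisk, rng: np.random.Generator) -> PlanarPoint:
    lo, hi, rlo, rhi = cfg.start_sector
    bearing = rng.uniform(lo, hi) % 360.0
    rmax = min(rhi, disk.radius_m)
    rng_m = rng.uniform(min(rlo, rmax), rmax)
    return polar_to_planar(PolarFix(bearing, rng_m))


def _rotate_about(p: np.ndarray, origin: np.ndarray, angle_rad: float) -> np.ndarray:
    c, s = math.cos(angle_rad), math.sin(angle_rad)
    d = p - origin
    return origin + np.array([c * d[0] - s * d[1], s * d[0] + c * d[1]])


_MAX_DISK_ATTEMPTS = 100
_MAX_REGEN = 1000
_DEFLECT_STEP_DEG = 5.0
_DEFLECT_MAX_STEPS = 72


def _shrink_to_disk(
    start: np.ndarray, mid: np.ndarray, end: np.ndarray, disk: DetectionDisk
) -> tuple[np.ndarray, np.ndarray]:
    """Scale mid/end toward start by the largest factor keeping both in the disk.

    Scaling about the start preserves the start→end bearing exactly, so the
    containment fallback never biases the bearing distribution.
    """
    center = np.array(disk.center.as_tuple())
    d = start - center
    s = 1.0
    for p in (mid, end):
        v = p - start
        vv = float(v @ v)
        if vv == 0:
            continue
        dv = float(d @ v)
        disc = dv * dv + vv * (disk.radius_m**2 - float(d @ d))
        s_p = (-dv + math.sqrt(max(disc, 0.0))) / vv  # |start| < R so disc > 0
        s = min(s, s_p * 0.999)
    return start + s * (mid - start), start + s * (end - start)


def _draw_candidate(
    cfg: SyntheticConfig, disk: DetectionDisk, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One start/mid/end triple inside the disk.

    The trajectory heading is drawn once; containment failures redraw only
    the leg geometry (lengths, wiggle, jitter) and, as a last resort, the
    whole polyline is shrunk about its start.  Keeping the heading fixed
    here is what lets the emitted bearing distribution track the requested
    von Mises concentration even for starts near the disk rim.
    """
    start = np.array(_sample_start(cfg, disk, rng).as_tuple())
    mu = math.radians(cfg.effective_mean_bearing)
    kappa = cfg.effective_kappa
    heading = rng.vonmises(mu, kappa) if kappa > 0 else rng.uniform(-math.pi, math.pi)
    for attempt in range(_MAX_DISK_ATTEMPTS):
        b1 = rng.vonmises(heading, cfg.leg_bearing_kappa)
        b2 = rng.vonmises(heading, cfg.leg_bearing_kappa)
        l1, l2 = rng.lognormal(cfg.leg_length_log_mean, cfg.leg_length_log_sigma, 2)
        jitter = rng.normal(0.0, cfg.mid_jitter_m, 2)
        mid = start + l1 * _unit(b1) + jitter
        end = mid + l2 * _unit(b2)
        if disk.contains(PlanarPoint(*mid)) and disk.contains(PlanarPoint(*end)):
            return start, mid, end
    mid, end = _shrink_to_disk(start, mid, end, disk)
    return start, mid, end


def _deflect(
    start: np.ndarray,
    mid: np.ndarray,
    end: np.ndarray,
    buffered,
    centroid: np.ndarray,
    disk: DetectionDisk,
) -> tuple[np.ndarray, np.ndarray] | None:
    """Rotate mid/end about start, away from the farm centroid, until clear.

    Returns the rotated (mid, end) or None when no rotation within the step
    budget clears the buffered polygon while staying inside the disk.
    """
    ang_end = math.atan2(end[1] - start[1], end[0] - start[0])
    ang_c = math.atan2(centroid[1] - start[1], centroid[0] - start[0])
    delta = (ang_end - ang_c + math.pi) % (2 * math.pi) - math.pi
    sign = 1.0 if delta >= 0 else -1.0
    for k in range(1, _DEFLECT_MAX_STEPS + 1):
        a = sign * math.radians(_DEFLECT_STEP_DEG * k)
        m2 = _rotate_about(mid, start, a)
        e2 = _rotate_about(end, start, a)
        if not (disk.contains(PlanarPoint(*m2)) and disk.contains(PlanarPoint(*e2))):
            continue
        line = shapely.linestrings([start, m2, e2])
        if not shapely.intersects(line, buffered):
            return m2, e2
    return None


def generate_trajectories(
    cfg: SyntheticConfig,
    disk: DetectionDisk | None = None,
    poly: FarmPolygon | None = None,
) -> TrajectorySet:
    """Generate a radar-like trajectory set; deterministic given ``cfg.seed``.

    All fixes lie within the detection disk.  With ``avoidance="deflect"``
    the returned set has zero intersections with ``poly`` by construction
    (each offending trajectory is rotated clear of the buffered polygon or,
    failing that, regenerated).
    """
    disk = disk or DetectionDisk()
    if cfg.avoidance == "deflect" and poly is None:
        raise ValidationError("avoidance='deflect' requires a farm polygon")
    rng = np.random.default_rng(cfg.seed)
    buffered = centroid = None
    if cfg.avoidance == "deflect":
        buffered = poly.shapely.buffer(cfg.deflect_buffer_m)
        shapely.prepare(buffered)
        centroid = np.array(poly.centroid.as_tuple())

    out: list[Trajectory] = []
    regens = 0
    for i in range(cfg.n_trajectories):
        while True:
            start, mid, end = _draw_candidate(cfg, disk, rng)
            if buffered is not None and shapely.intersects(
                shapely.linestrings([start, mid, end]), buffered
            ):
                rotated = _deflect(start, mid, end, buffered, centroid, disk)
                if rotated is None:
                    regens += 1
                    logger.info("trajectory %d: deflection failed, regenerating", i)
                    if regens > _MAX_REGEN:
                        raise ValidationError(
                            "avoidance re-routing failed repeatedly; the start "
                            "sector may lie inside the farm buffer"
                        )
                    continue
                mid, end = rotated
            break
        out.append(
            Trajectory(
                id=f"{cfg.season}-{i:04d}",
                start=PlanarPoint(*start),
                mid=PlanarPoint(*mid),
                end=PlanarPoint(*end),
                season=cfg.season,
            )
        )
    return TrajectorySet(out, season=cfg.season)


def generate_model1_set(
    n_trajectories: int,
    disk: DetectionDisk | None = None,
    seed: int | np.random.Generator = 0,
    season: str = "other",
) -> TrajectorySet:
    """Trajectory set with all three fixes i.i.d. uniform by area in the disk.

    This preset coincides by construction with the Model 1 simulator (same
    area-uniform sampler), so testing such sets against Model 1 nulls is an
    exact type-I-error calibration of the randomization test.
    """
    disk = disk or DetectionDisk()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pts = _sample_disk(rng, disk, n_trajectories * 3).reshape(n_trajectories, 3, 2)
    return TrajectorySet(
        [
            Trajectory(
                id=f"{season}-{i:04d}",
                start=PlanarPoint(*pts[i, 0]),
                mid=PlanarPoint(*pts[i, 1]),
                end=PlanarPoint(*pts[i, 2]),
                season=season,
            )
            for i in range(n_trajectories)
        ],
        season=season,
    )
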