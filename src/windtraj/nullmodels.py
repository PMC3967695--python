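"""Trajectory-randomization null models and the rank-based randomization test.

Five nested null models re-simulate each observed trajectory while retaining
progressively more of its structure:

======  ==========================  =====================================
model   retained fixes              free fixes
======  ==========================  =====================================
1       none                        start, mid, end uniform in the disk
2       start                       mid, end uniform in the disk
3       start, mid                  end uniform in the disk
4       start, end                  mid uniform in the axis-aligned
                                    rectangle spanned by start and end
5       start, mid                  end uniform in the disk, strictly
                                    south of both retained points
======  ==========================  =====================================

Free points are sampled uniformly *by area* — the least-informative reading
of "randomly generated within the detection radius".  Model 5 encodes a
seasonal southbound tendency and is restricted to seasons declared
directional (fall in the original application).

For each of the (default 10,000) replicates every trajectory is
re-simulated and one intersections/km value is computed; the replicate's
own total simulated length is the denominator, since the models change
trajectory lengths.  The two-tailed test rejects the no-avoidance
hypothesis when the observed index falls among the ⌊α/2·R⌋ smallest or
largest null values (250 per tail at R = 10,000, α = 0.05); ties count as
extreme.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .geometry import (
    DetectionDisk,
    FarmPolygon,
    PlanarPoint,
    Trajectory,
    TrajectorySet,
    ValidationError,
    count_crossing_events,
    intersection_mask,
    intersections_per_km,
)

__all__ = [
    "NullModelSpec",
    "RunConfig",
    "SimulationResult",
    "sample_point_in_disk",
    "simulate_trajectory",
    "simulate_replicates",
    "run_null_model",
    "central_interval",
    "randomization_test",
    "rng_for_model",
]

logger = logging.getLogger(__name__)

_MAX_REJECTION_ATTEMPTS = 1_000_000  # per point, model-5 southern sampling


@dataclass(frozen=True)
class NullModelSpec:
    """Which fixes a null model retains and how free fixes are constrained."""

    model_id: int
    retain_start: bool
    retain_mid: bool
    retain_end: bool
    mid_constraint: Literal["none", "bounding_rectangle_of_start_end"] = "none"
    end_constraint: Literal["none", "south_of_start_and_mid"] = "none"

    _TABLE = {
        1: dict(retain_start=False, retain_mid=False, retain_end=False),
        2: dict(retain_start=True, retain_mid=False, retain_end=False),
        3: dict(retain_start=True, retain_mid=True, retain_end=False),
        4: dict(
            retain_start=True,
            retain_mid=False,
            retain_end=True,
            mid_constraint="bounding_rectangle_of_start_end",
        ),
        5: dict(
            retain_start=True,
            retain_mid=True,
            retain_end=False,
            end_constraint="south_of_start_and_mid",
        ),
    }

    @classmethod
    def from_id(cls, model_id: int) -> "NullModelSpec":
        try:
            kw = cls._TABLE[model_id]
        except KeyError:
            raise ValidationError(f"unknown null model id {model_id}; valid ids are 1-5")
        return cls(model_id=model_id, **kw)

    @property
    def requires_directional_season(self) -> bool:
        return self.end_constraint == "south_of_start_and_mid"


@dataclass
class RunConfig:
    """Monte-Carlo run parameters.

    ``directional_seasons`` lists the season labels for which the
    south-constrained Model 5 is permitted; ``allow_model5`` overrides the
    restriction explicitly instead of silently skipping the model.
    """

    replicates: int = 10_000
    alpha: float = 0.05
    seed: int = 0
    disk: DetectionDisk = field(default_factory=DetectionDisk)
    models: tuple[int, ...] = (1, 2, 3, 4, 5)
    per_crossing_counting: bool = False
    per_replicate_denominator: bool = True
    directional_seasons: tuple[str, ...] = ("fall",)
    allow_model5: bool = False

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError(f"alpha must be in (0, 1), got {self.alpha}")
        bad = [m for m in self.models if m not in (1, 2, 3, 4, 5)]
        if bad:
            raise ValidationError(f"unknown model ids {bad}")

    def validate_for_season(self, season: str) -> None:
        for m in self.models:
            spec = NullModelSpec.from_id(m)
            if spec.requires_directional_season and not self.allow_model5:
                if season not in self.directional_seasons:
                    raise ValidationError(
                        f"model {m} encodes a directional (southbound) tendency and is "
                        f"restricted to seasons {self.directional_seasons}; season "
                        f"{season!r} is not among them. Pass allow_model5=True "
                        "(--allow-model5) to override."
                    )


@dataclass
class SimulationResult:
    """Null distribution of intersections/km plus the observed index and decision."""

    model_id: int
    observed_index: float
    null_values: np.ndarray
    interval_95: tuple[float, float]
    rejected: bool
    tail: Literal["low", "high", "none"]
    rank_of_observed: int
    replicates: int
    seed: int
    n_redrawn_replicates: int = 0


def rng_for_model(seed: int, model_id: int) -> np.random.Generator:
    """Deterministic per-model substream: adding a model never perturbs another."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(model_id,)))


def _sample_disk(rng: np.random.Generator, disk: DetectionDisk, size: int) -> np.ndarray:
    """(size, 2) points uniform by area over the disk (radius = R*sqrt(u))."""
    r = disk.radius_m * np.sqrt(rng.random(size))
    theta = rng.uniform(0.0, 2.0 * np.pi, size)
    return np.column_stack(
        (disk.center.x + r * np.cos(theta), disk.center.y + r * np.sin(theta))
    )


def sample_point_in_disk(disk: DetectionDisk, rng: np.random.Generator) -> PlanarPoint:
    """One point uniform by area over the detection disk."""
    x, y = _sample_disk(rng, disk, 1)[0]
    return PlanarPoint(float(x), float(y))


def _sample_south_of(
    rng: np.random.Generator, disk: DetectionDisk, y_max: np.ndarray
) -> np.ndarray:
    """For each y_max[i], a disk-uniform point with y strictly below y_max[i].

    Rejection sampling; the feasible region is the disk cut by a horizontal
    line, empty only when y_max is at (or below) the southern rim.
    """
    y_rim = disk.center.y - disk.radius_m
    if np.any(y_max <= y_rim):
        raise ValidationError(
            "model 5 has an empty feasible region: retained points lie on the "
            "southern rim of the detection disk"
        )
    n = len(y_max)
    out = np.empty((n, 2))
    pending = np.arange(n)
    attempts = 0
    while pending.size:
        draws = _sample_disk(rng, disk, pending.size)
        ok = draws[:, 1] < y_max[pending]
        out[pending[ok]] = draws[ok]
        pending = pending[~ok]
        attempts += 1
        if attempts > _MAX_REJECTION_ATTEMPTS:
            raise ValidationError(
                "model 5 rejection sampling exceeded the attempt cap; feasible "
                "region is vanishingly small"
            )
    return out


def simulate_replicates(
    model: NullModelSpec,
    observed_coords: np.ndarray,
    disk: DetectionDisk,
    rng: np.random.Generator,
    replicates: int,
) -> np.ndarray:
    """Simulate ``replicates`` copies of every trajectory under one null model.

    Parameters
    ----------
    observed_coords : (n, 3, 2) array of the observed start/mid/end points.

    Returns
    -------
    (replicates, n, 3, 2) array; retained coordinates are copied bit-for-bit
    from the observed array.
    """
    obs = np.asarray(observed_coords, dtype=float)
    n = obs.shape[0]
    R = replicates
    sim = np.broadcast_to(obs, (R, n, 3, 2)).copy()

    free_slots = [
        i
        for i, retained in enumerate(
            (model.retain_start, model.retain_mid, model.retain_end)
        )
        if not retained
    ]
    for slot in free_slots:
        if slot == 1 and model.mid_constraint == "bounding_rectangle_of_start_end":
            # uniform in the axis-aligned box of start and end; degenerate
            # boxes collapse to the segment (or the shared point) naturally
            u = rng.random((R, n, 2))
            sim[:, :, 1, :] = sim[:, :, 0, :] + u * (sim[:, :, 2, :] - sim[:, :, 0, :])
        elif slot == 2 and model.end_constraint == "south_of_start_and_mid":
            y_max = np.minimum(obs[:, 0, 1], obs[:, 1, 1])  # min(y_start, y_mid)
            pts = _sample_south_of(rng, disk, np.tile(y_max, R))
            sim[:, :, 2, :] = pts.reshape(R, n, 2)
        else:
            sim[:, :, slot, :] = _sample_disk(rng, disk, R * n).reshape(R, n, 2)
    return sim


def simulate_trajectory(
    model: NullModelSpec,
    observed: Trajectory,
    disk: DetectionDisk,
    rng: np.random.Generator,
) -> Trajectory:
    """One re-simulated trajectory; retained fixes equal the observed ones exactly."""
    for p in observed.points:
        if not disk.contains(p):
            raise ValidationError(
                f"trajectory {observed.id!r} has a fix outside the detection disk"
            )
    sim = simulate_replicates(model, observed.coords()[None], disk, rng, 1)[0, 0]
    return Trajectory(
        id=observed.id,
        start=PlanarPoint(*sim[0]),
        mid=PlanarPoint(*sim[1]),
        end=PlanarPoint(*sim[2]),
        season=observed.season,
    )


def _replicate_lengths_km(sim: np.ndarray) -> np.ndarray:
    """Total polyline length per replicate, km, for a (R, n, 3, 2) array."""
    seg = np.diff(sim, axis=2)  # (R, n, 2, 2)
    return np.linalg.norm(seg, axis=3).sum(axis=(1, 2)) / 1000.0


def _replicate_counts(
    sim: np.ndarray, poly: FarmPolygon, per_crossing: bool
) -> np.ndarray:
    R, n = sim.shape[:2]
    if not per_crossing:
        mask = intersection_mask(sim.reshape(R * n, 3, 2), poly)
        return mask.reshape(R, n).sum(axis=1)
    # sensitivity path: count separate entries; loop is acceptable here
    counts = np.empty(R, dtype=int)
    for i in range(R):
        ts = TrajectorySet(
            [
                Trajectory(str(j), *(PlanarPoint(*p) for p in sim[i, j]))
                for j in range(n)
            ]
        )
        counts[i] = count_crossing_events(ts, poly)
    return counts


def run_null_model(
    ts: TrajectorySet,
    poly: FarmPolygon,
    model: NullModelSpec | int,
    cfg: RunConfig,
) -> SimulationResult:
    """Full Monte-Carlo run of one null model against an observed trajectory set."""
    if len(ts) == 0:
        raise ValidationError("cannot run a null model on an empty trajectory set")
    if isinstance(model, int):
        model = NullModelSpec.from_id(model)
    rng = rng_for_model(cfg.seed, model.model_id)
    obs_coords = ts.coords()

    observed_index = intersections_per_km(ts, poly, per_crossing=cfg.per_crossing_counting)
    observed_total_km = ts.total_length_km

    sim = simulate_replicates(model, obs_coords, cfg.disk, rng, cfg.replicates)
    counts = _replicate_counts(sim, poly, cfg.per_crossing_counting)
    lengths = _replicate_lengths_km(sim)

    # zero-length replicates have probability zero under continuous sampling;
    # redraw defensively and log the event
    n_redrawn = 0
    zero = np.flatnonzero(lengths <= 0.0)
    while zero.size:
        n_redrawn += zero.size
        logger.warning("redrawing %d zero-length replicate(s) for model %d", zero.size, model.model_id)
        redo = simulate_replicates(model, obs_coords, cfg.disk, rng, zero.size)
        counts[zero] = _replicate_counts(redo, poly, cfg.per_crossing_counting)
        lengths[zero] = _replicate_lengths_km(redo)
        zero = zero[lengths[zero] <= 0.0]

    denom = lengths if cfg.per_replicate_denominator else np.full_like(lengths, observed_total_km)
    null_values = counts / denom

    interval = central_interval(null_values, 0.95)
    rejected, tail, rank = randomization_test(observed_index, null_values, cfg.alpha)
    return SimulationResult(
        model_id=model.model_id,
        observed_index=observed_index,
        null_values=null_values,
        interval_95=interval,
        rejected=rejected,
        tail=tail,
        rank_of_observed=rank,
        replicates=cfg.replicates,
        seed=cfg.seed,
        n_redrawn_replicates=n_redrawn,
    )


def central_interval(
    values: Sequence[float] | np.ndarray, coverage: float = 0.95
) -> tuple[float, float]:
    """Central order-statistic interval: k-th smallest to k-th largest value.

    k = ⌊(1 − coverage)/2 · n⌋ floored at 1, so for n = 10,000 at 95%
    coverage the bounds are the 250th smallest and 250th largest values.
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n < 2:
        raise ValidationError("central interval needs at least 2 values")
    k = max(1, math.floor((1.0 - coverage) / 2.0 * n))
    return (float(v[k - 1]), float(v[n - k]))


def randomization_test(
    observed_index: float,
    null_values: Sequence[float] | np.ndarray,
    alpha: float,
) -> tuple[bool, Literal["low", "high", "none"], int]:
    """Two-tailed rank test of the observed index against the null distribution.

    Rejects when the observed value falls among the k = ⌊α/2 · n⌋ smallest
    (tail "low") or largest (tail "high") null values; ties count as extreme.
    Returns (rejected, tail, rank) where rank is 1 + the number of null
    values strictly below the observed index.
    """
    v = np.sort(np.asarray(null_values, dtype=float))
    n = v.size
    if n == 0:
        raise ValidationError("randomization test needs a nonempty null distribution")
    k = math.floor(alpha / 2.0 * n)
    if k == 0:
        raise ValidationError(
            f"alpha/2 = {alpha / 2} gives an empty rejection region for n = {n}; "
            "increase the number of replicates"
        )
    rank = int(np.sum(v < observed_index)) + 1
    if observed_index <= v[k - 1]:
        return True, "low", rank
    if observed_index >= v[n - k]:
        return True, "high", rank
    return False, "none", rank
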