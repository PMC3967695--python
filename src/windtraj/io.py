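"""File formats: trajectory/turbine CSV dialects, GeoJSON export, run config.

Trajectory CSV: one row per radar fix with columns
``season, trajectory_id, role, bearing_deg, range_m`` where role is one of
start/mid/end; every trajectory needs exactly one fix per role.  Turbine
CSV: ``turbine_id, x_m, y_m`` in the radar-centred planar frame.  GeoJSON
features carry the local east/north metric frame in their properties (no
geographic CRS is implied).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Iterable

import pandas as pd

from .geometry import (
    FarmPolygon,
    PlanarPoint,
    PolarFix,
    Trajectory,
    TrajectorySet,
    ValidationError,
    planar_to_polar,
    polar_to_planar,
)

__all__ = [
    "read_trajectories",
    "write_trajectories",
    "read_turbines",
    "write_turbines",
    "to_geojson",
    "write_geojson",
    "read_config_file",
]

_ROLES = ("start", "mid", "end")
_TRAJ_COLUMNS = ["season", "trajectory_id", "role", "bearing_deg", "range_m"]

_FRAME_METADATA = {
    "frame": "local tangent plane, x east / y north, metres",
    "origin": "radar station",
}


class TrajectoryParseError(ValidationError):
    """Aggregated per-trajectory parse failures."""

    def __init__(self, errors: dict[str, str]):
        self.errors = dict(errors)
        lines = "; ".join(f"{tid}: {msg}" for tid, msg in sorted(self.errors.items()))
        super().__init__(f"{len(self.errors)} malformed trajectory record(s): {lines}")


def read_trajectories(path: str | Path, season: str | None = None) -> TrajectorySet:
    """Read the trajectory CSV dialect into a :class:`TrajectorySet`.

    Incomplete or inconsistent triples are collected and reported together
    in a :class:`TrajectoryParseError` rather than failing one at a time.
    ``season`` optionally filters to one season label.
    """
    df = pd.read_csv(path, dtype={"trajectory_id": str})
    missing = [c for c in _TRAJ_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"trajectory CSV is missing columns {missing}")
    if season is not None:
        df = df[df["season"] == season]
    errors: dict[str, str] = {}
    trajectories: list[Trajectory] = []
    seasons: list[str] = []
    for tid, grp in df.groupby("trajectory_id", sort=False):
        roles = grp["role"].tolist()
        if sorted(roles) != sorted(_ROLES):
            errors[str(tid)] = f"expected one fix per role {_ROLES}, got {roles}"
            continue
        if grp["season"].nunique() != 1:
            errors[str(tid)] = f"inconsistent season labels {sorted(grp['season'].unique())}"
            continue
        try:
            by_role = {
                row.role: polar_to_planar(
                    PolarFix(float(row.bearing_deg), float(row.range_m))
                )
                for row in grp.itertuples()
            }
        except (ValidationError, ValueError) as exc:
            errors[str(tid)] = str(exc)
            continue
        trajectories.append(
            Trajectory(
                id=str(tid),
                start=by_role["start"],
                mid=by_role["mid"],
                end=by_role["end"],
                season=str(grp["season"].iloc[0]),
            )
        )
        seasons.append(str(grp["season"].iloc[0]))
    if errors:
        raise TrajectoryParseError(errors)
    label = season if season is not None else (seasons[0] if len(set(seasons)) == 1 else "mixed")
    return TrajectorySet(trajectories, season=label or "other")


def write_trajectories(ts: TrajectorySet, path: str | Path) -> None:
    """Write a trajectory set in the polar-fix CSV dialect."""
    rows = []
    for t in ts:
        for role, p in zip(_ROLES, t.points):
            fix = planar_to_polar(p)
            rows.append(
                {
                    "season": t.season,
                    "trajectory_id": t.id,
                    "role": role,
                    "bearing_deg": fix.bearing_deg,
                    "range_m": fix.range_m,
                }
            )
    pd.DataFrame(rows, columns=_TRAJ_COLUMNS).to_csv(path, index=False)


def read_turbines(path: str | Path) -> list[PlanarPoint]:
    df = pd.read_csv(path)
    missing = [c for c in ("turbine_id", "x_m", "y_m") if c not in df.columns]
    if missing:
        raise ValidationError(f"turbine CSV is missing columns {missing}")
    return [PlanarPoint(float(r.x_m), float(r.y_m)) for r in df.itertuples()]


def write_turbines(turbines: Iterable[PlanarPoint], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"turbine_id": f"T{i:03d}", "x_m": p.x, "y_m": p.y}
            for i, p in enumerate(turbines, start=1)
        ]
    ).to_csv(path, index=False)


def to_geojson(
    ts: TrajectorySet | None = None,
    poly: FarmPolygon | None = None,
    radar: PlanarPoint | None = None,
) -> dict[str, Any]:
    """FeatureCollection of trajectories (LineString), farm (Polygon), radar (Point)."""
    features: list[dict[str, Any]] = []
    if ts is not None:
        for t in ts:
            features.append(
                {
                    "type": "Feature",
                    "geometry": {
                        "type": "LineString",
                        "coordinates": [[p.x, p.y] for p in t.points],
                    },
                    "properties": {
                        "kind": "trajectory",
                        "trajectory_id": t.id,
                        "season": t.season,
                        "degenerate": t.is_degenerate,
                        **_FRAME_METADATA,
                    },
                }
            )
    if poly is not None:
        ring = [[p.x, p.y] for p in poly.vertices]
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {"kind": "farm_polygon", **_FRAME_METADATA},
            }
        )
    if radar is not None:
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [radar.x, radar.y]},
                "properties": {"kind": "radar", **_FRAME_METADATA},
            }
        )
    return {"type": "FeatureCollection", "features": features}


def write_geojson(path: str | Path, **kwargs: Any) -> None:
    Path(path).write_text(json.dumps(to_geojson(**kwargs), indent=1))


_CONFIG_PARSERS = {
    "detection_radius_m": float,
    "replicates": int,
    "alpha": float,
    "seed": int,
    "models": lambda s: tuple(int(m) for m in s.replace(",", " ").split()),
    "per_crossing_counting": lambda s: s.strip().lower() in ("1", "true", "yes"),
    "per_replicate_denominator": lambda s: s.strip().lower() in ("1", "true", "yes"),
    "allow_model5": lambda s: s.strip().lower() in ("1", "true", "yes"),
}


def read_config_file(path: str | Path) -> dict[str, Any]:
    """Parse a ``key = value`` run-config file; unknown keys are rejected."""
    out: dict[str, Any] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValidationError(f"config line {lineno}: expected 'key = value', got {raw!r}")
        key, _, value = line.partition("=")
        key = key.strip()
        if key not in _CONFIG_PARSERS:
            raise ValidationError(f"config line {lineno}: unknown key {key!r}")
        out[key] = _CONFIG_PARSERS[key](value.strip())
    return out
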