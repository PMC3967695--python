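"""End-to-end orchestration: load data, compute the observed index, run the
configured null models, apply the randomization test, and emit the report.

The run report is a machine-readable analogue of a null-model summary
table: one row per model with the observed intersections/km, the central
95% range of the null distribution, and the two-tailed test decision,
plus the season's circular summary of flight bearings.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from . import io as wio
from .circular import CircularSummary, circular_summary, trajectory_bearing
from .geometry import (
    FarmPolygon,
    PlanarPoint,
    TrajectorySet,
    ValidationError,
    build_farm_polygon,
    count_crossing_events,
    count_intersections,
    index_from_counts,
)
from .nullmodels import RunConfig, SimulationResult, run_null_model

__all__ = ["RunReport", "analyze_set", "run_analysis", "write_report"]

logger = logging.getLogger(__name__)


@dataclass
class RunReport:
    """Everything one analysis run produced, ready for serialization."""

    season: str
    n_trajectories: int
    total_length_km: float
    n_intersections: int
    observed_index: float
    circular: CircularSummary | None
    results: list[SimulationResult]
    config: RunConfig
    degenerate_trajectory_ids: list[str] = field(default_factory=list)
    undefined_bearing_ids: list[str] = field(default_factory=list)

    def to_dict(self, include_null_values: bool = False) -> dict[str, Any]:
        d: dict[str, Any] = {
            "season": self.season,
            "n_trajectories": self.n_trajectories,
            "total_length_km": self.total_length_km,
            "n_intersections": self.n_intersections,
            "observed_index": self.observed_index,
            "circular": None
            if self.circular is None
            else {
                "mu_deg": None if not self.circular.mu_defined else self.circular.mu_deg,
                "r": self.circular.r,
                "n": self.circular.n,
            },
            "config": {
                "replicates": self.config.replicates,
                "alpha": self.config.alpha,
                "seed": self.config.seed,
                "detection_radius_m": self.config.disk.radius_m,
                "models": list(self.config.models),
                "per_crossing_counting": self.config.per_crossing_counting,
                "per_replicate_denominator": self.config.per_replicate_denominator,
            },
            "degenerate_trajectory_ids": self.degenerate_trajectory_ids,
            "undefined_bearing_ids": self.undefined_bearing_ids,
            "models": [],
        }
        for res in self.results:
            row: dict[str, Any] = {
                "model_id": res.model_id,
                "observed_index": res.observed_index,
                "interval_low": res.interval_95[0],
                "interval_high": res.interval_95[1],
                "rejected": bool(res.rejected),
                "tail": res.tail,
                "rank_of_observed": res.rank_of_observed,
                "replicates": res.replicates,
                "seed": res.seed,
                "n_redrawn_replicates": res.n_redrawn_replicates,
            }
            if include_null_values:
                row["null_values"] = np.asarray(res.null_values).tolist()
            d["models"].append(row)
        return d

    def models_frame(self) -> pd.DataFrame:
        """One row per model — the machine-readable twin of a summary table."""
        return pd.DataFrame(
            [
                {
                    "model_id": r.model_id,
                    "observed_index": r.observed_index,
                    "interval_low": r.interval_95[0],
                    "interval_high": r.interval_95[1],
                    "rejected": r.rejected,
                    "tail": r.tail,
                    "rank_of_observed": r.rank_of_observed,
                    "replicates": r.replicates,
                    "seed": r.seed,
                }
                for r in self.results
            ]
        )


def analyze_set(ts: TrajectorySet, poly: FarmPolygon, cfg: RunConfig) -> RunReport:
    """Run the full analysis on an in-memory trajectory set."""
    if len(ts) == 0:
        raise ValidationError("cannot analyse an empty trajectory set")
    cfg.validate_for_season(ts.season)

    degenerate = ts.degenerate_ids
    if degenerate:
        logger.warning("degenerate (zero-length) trajectories retained: %s", degenerate)

    if cfg.per_crossing_counting:
        n_inter = count_crossing_events(ts, poly)
    else:
        n_inter = count_intersections(ts, poly)
    total_km = ts.total_length_km
    observed_index = index_from_counts(n_inter, total_km)

    bearings = []
    undefined: list[str] = []
    for t in ts:
        try:
            bearings.append(trajectory_bearing(t))
        except ValidationError:
            undefined.append(t.id)
    if undefined:
        logger.warning("trajectories excluded from circular summary (start == end): %s", undefined)
    circ = circular_summary(bearings) if bearings else None

    results = [run_null_model(ts, poly, m, cfg) for m in cfg.models]
    return RunReport(
        season=ts.season,
        n_trajectories=len(ts),
        total_length_km=total_km,
        n_intersections=n_inter,
        observed_index=observed_index,
        circular=circ,
        results=results,
        config=cfg,
        degenerate_trajectory_ids=degenerate,
        undefined_bearing_ids=undefined,
    )


def run_analysis(
    trajectory_csv: str | Path,
    turbine_csv: str | Path,
    config: RunConfig | None = None,
    *,
    season: str | None = None,
    farm_ring: Sequence[PlanarPoint] | None = None,
) -> RunReport:
    """Load the CSV inputs, build the farm polygon, and analyse.

    ``farm_ring`` optionally supplies an explicit perimeter ring, overriding
    the convex hull of the turbine positions.
    """
    cfg = config or RunConfig()
    ts = wio.read_trajectories(trajectory_csv, season=season)
    turbines = wio.read_turbines(turbine_csv)
    poly = FarmPolygon(farm_ring) if farm_ring is not None else build_farm_polygon(turbines)
    return analyze_set(ts, poly, cfg)


def write_report(
    report: RunReport,
    out_dir: str | Path,
    *,
    dump_null_values: bool = False,
) -> dict[str, Path]:
    """Serialize a run: report.json, models.tsv, summary.tsv, optional null dumps."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["json"] = out / "report.json"
    paths["json"].write_text(json.dumps(report.to_dict(), indent=1))

    paths["models_tsv"] = out / "models.tsv"
    report.models_frame().to_csv(paths["models_tsv"], sep="\t", index=False)

    circ = report.circular
    summary = pd.DataFrame(
        [
            {
                "season": report.season,
                "n_trajectories": report.n_trajectories,
                "total_length_km": report.total_length_km,
                "n_intersections": report.n_intersections,
                "observed_index": report.observed_index,
                "n_bearings": None if circ is None else circ.n,
                "mu_deg": None if circ is None or not circ.mu_defined else circ.mu_deg,
                "r": None if circ is None else circ.r,
            }
        ]
    )
    paths["summary_tsv"] = out / "summary.tsv"
    summary.to_csv(paths["summary_tsv"], sep="\t", index=False)

    if dump_null_values:
        for res in report.results:
            p = out / f"null_values_model{res.model_id}.txt"
            np.savetxt(p, np.asarray(res.null_values), fmt="%.10g")
            paths[f"nulls_model{res.model_id}"] = p
    return paths
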