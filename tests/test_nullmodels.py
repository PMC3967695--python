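"""Null models: samplers, retention, constraints, interval and test rules."""

import numpy as np
import pytest

from windtraj.geometry import (
    DetectionDisk,
    FarmPolygon,
    PlanarPoint,
    TrajectorySet,
    ValidationError,
)
from windtraj.nullmodels import (
    NullModelSpec,
    RunConfig,
    central_interval,
    randomization_test,
    rng_for_model,
    run_null_model,
    sample_point_in_disk,
    simulate_replicates,
    simulate_trajectory,
)

from conftest import make_trajectory


@pytest.fixture(scope="module")
def observed_set() -> TrajectorySet:
    rng = np.random.default_rng(99)
    return TrajectorySet(
        [make_trajectory(i, *rng.uniform(-3000, 3000, (3, 2))) for i in range(20)]
    )


class TestDiskSampler:
    def test_area_uniform_moments(self, disk):
        """Area-uniform sampling has E[d^2] = R^2/2 and P(y > 0) = 1/2."""
        from windtraj.nullmodels import _sample_disk

        rng = np.random.default_rng(0)
        p = sample_point_in_disk(disk, rng)  # scalar API shares the sampler
        assert disk.contains(p)
        pts = _sample_disk(rng, disk, 100_000)
        d2 = (pts**2).sum(axis=1)
        assert d2.mean() == pytest.approx(disk.radius_m**2 / 2, rel=0.01)
        assert np.all(np.sqrt(d2) <= disk.radius_m)
        frac_north = (pts[:, 1] > 0).mean()
        assert abs(frac_north - 0.5) < 3 * 0.5 / np.sqrt(len(pts))


class TestModelSpecs:
    @pytest.mark.parametrize(
        "model_id,retained",
        [
            (1, (False, False, False)),
            (2, (True, False, False)),
            (3, (True, True, False)),
            (4, (True, False, True)),
            (5, (True, True, False)),
        ],
    )
    def test_retention_table(self, model_id, retained):
        spec = NullModelSpec.from_id(model_id)
        assert (spec.retain_start, spec.retain_mid, spec.retain_end) == retained

    def test_unknown_id_rejected(self):
        with pytest.raises(ValidationError):
            NullModelSpec.from_id(6)


class TestSimulateTrajectory:
    @pytest.mark.parametrize("model_id", [2, 3, 4, 5])
    def test_retention_identity_bit_for_bit(self, model_id, disk, observed_set):
        spec = NullModelSpec.from_id(model_id)
        rng = rng_for_model(1, model_id)
        sim = simulate_replicates(spec, observed_set.coords(), disk, rng, 50)
        obs = observed_set.coords()
        slots = [
            i
            for i, keep in enumerate((spec.retain_start, spec.retain_mid, spec.retain_end))
            if keep
        ]
        for s in slots:
            assert np.array_equal(sim[:, :, s, :], np.broadcast_to(obs[:, s, :], sim[:, :, s, :].shape))

    def test_free_points_stay_in_disk(self, disk, observed_set):
        for model_id in (1, 2, 3, 5):
            spec = NullModelSpec.from_id(model_id)
            sim = simulate_replicates(
                spec, observed_set.coords(), disk, rng_for_model(2, model_id), 20
            )
            free = [
                i
                for i, keep in enumerate(
                    (spec.retain_start, spec.retain_mid, spec.retain_end)
                )
                if not keep
            ]
            for s in free:
                d = np.linalg.norm(sim[:, :, s, :], axis=-1)
                assert np.all(d <= disk.radius_m * (1 + 1e-12))

    def test_model4_rectangle_constraint_and_moments(self, disk):
        """All mids in the start/end bounding box; empirical mean near centre."""
        t = make_trajectory("t", (0, 0), (123, 456), (1000, 500))
        ts = TrajectorySet([t])
        spec = NullModelSpec.from_id(4)
        sim = simulate_replicates(spec, ts.coords(), disk, np.random.default_rng(3), 10_000)
        mids = sim[:, 0, 1, :]
        assert np.all((mids[:, 0] >= 0) & (mids[:, 0] <= 1000))
        assert np.all((mids[:, 1] >= 0) & (mids[:, 1] <= 500))
        se = np.array([1000, 500]) / np.sqrt(12) / np.sqrt(len(mids))
        assert np.all(np.abs(mids.mean(axis=0) - [500, 250]) < 3 * se)

    def test_model4_degenerate_box_collapses_to_segment(self, disk):
        t = make_trajectory("t", (100, 0), (55, 5), (100, 800))  # shared x
        spec = NullModelSpec.from_id(4)
        sim = simulate_replicates(spec, t.coords()[None], disk, np.random.default_rng(4), 1000)
        mids = sim[:, 0, 1, :]
        assert np.all(mids[:, 0] == 100.0)
        assert np.all((mids[:, 1] >= 0) & (mids[:, 1] <= 800))

    def test_model5_ends_strictly_south(self, disk):
        t = make_trajectory("t", (-500, 800), (200, 300), (0, -1000))
        spec = NullModelSpec.from_id(5)
        sim = simulate_replicates(spec, t.coords()[None], disk, np.random.default_rng(5), 10_000)
        ends = sim[:, 0, 2, :]
        assert np.all(ends[:, 1] < 300.0)  # min(y_start, y_mid)
        assert np.all(np.linalg.norm(ends, axis=1) <= disk.radius_m)

    def test_model5_empty_region_errors(self, disk):
        rim = make_trajectory("rim", (0, -6000), (0, -6000 + 1e-9), (0, 0))
        with pytest.raises(ValidationError, match="southern rim"):
            simulate_trajectory(NullModelSpec.from_id(5), rim, disk, np.random.default_rng(6))

    def test_scalar_api_retains_observed(self, disk):
        t = make_trajectory("t", (10, 20), (30, 40), (50, 60), season="fall")
        out = simulate_trajectory(NullModelSpec.from_id(3), t, disk, np.random.default_rng(7))
        assert (out.start, out.mid) == (t.start, t.mid)
        assert out.end != t.end
        assert out.season == "fall"


class TestCentralInterval:
    def test_order_statistic_rule_n10000(self):
        low, high = central_interval(np.arange(1, 10_001), 0.95)
        assert (low, high) == (250.0, 9751.0)

    def test_order_statistic_rule_n100(self):
        low, high = central_interval(np.arange(1, 101), 0.95)
        assert (low, high) == (2.0, 99.0)

    def test_constant_values(self):
        assert central_interval([3.3] * 50) == (3.3, 3.3)

    def test_too_few_values(self):
        with pytest.raises(ValidationError):
            central_interval([1.0])


class TestRandomizationTest:
    def test_extreme_minimum(self):
        nulls = np.arange(1, 10_001, dtype=float)
        rejected, tail, rank = randomization_test(0.5, nulls, 0.05)
        assert (rejected, tail, rank) == (True, "low", 1)

    def test_central_value_not_rejected(self):
        nulls = np.arange(1, 10_001, dtype=float)
        rejected, tail, _ = randomization_test(5000.0, nulls, 0.05)
        assert (rejected, tail) == (False, "none")

    def test_inclusive_boundary_at_250th_smallest(self):
        nulls = np.arange(1, 10_001, dtype=float)
        rejected, tail, _ = randomization_test(250.0, nulls, 0.05)
        assert (rejected, tail) == (True, "low")
        rejected, tail, _ = randomization_test(251.0, nulls, 0.05)
        assert not rejected

    def test_high_tail(self):
        nulls = np.arange(1, 10_001, dtype=float)
        rejected, tail, _ = randomization_test(9751.0, nulls, 0.05)
        assert (rejected, tail) == (True, "high")

    def test_empty_rejection_region_errors(self):
        with pytest.raises(ValidationError, match="replicates"):
            randomization_test(1.0, np.arange(10.0), 0.05)


class TestRunNullModel:
    def test_full_coverage_polygon_counts_all(self, observed_set):
        big = FarmPolygon([(-1e5, -1e5), (1e5, -1e5), (1e5, 1e5), (-1e5, 1e5)])
        cfg = RunConfig(replicates=200, seed=1, models=(1,))
        res = run_null_model(observed_set, big, 1, cfg)
        # every simulated trajectory intersects, so each null value is N / length
        assert np.all(res.null_values > 0)
        n = len(observed_set)
        lengths = n / res.null_values
        assert np.all(lengths > 0)
        assert res.observed_index == pytest.approx(n / observed_set.total_length_km)

    def test_tiny_polygon_concentrates_near_zero(self, observed_set):
        tiny = FarmPolygon([(0, 0), (1e-3, 0), (1e-3, 1e-3), (0, 1e-3)])
        cfg = RunConfig(replicates=200, seed=2, models=(1,))
        res = run_null_model(observed_set, tiny, 1, cfg)
        assert np.median(res.null_values) == 0.0

    def test_seeded_determinism(self, observed_set, unit_square_km):
        cfg = RunConfig(replicates=100, seed=42, models=(2,))
        r1 = run_null_model(observed_set, unit_square_km, 2, cfg)
        r2 = run_null_model(observed_set, unit_square_km, 2, cfg)
        assert np.array_equal(r1.null_values, r2.null_values)
        assert r1.interval_95 == r2.interval_95

    def test_per_model_substreams_independent_of_model_list(self, observed_set, unit_square_km):
        """Model 3's draws are the same whether or not model 1 also runs."""
        cfg_a = RunConfig(replicates=50, seed=7, models=(3,))
        cfg_b = RunConfig(replicates=50, seed=7, models=(1, 3))
        res_a = run_null_model(observed_set, unit_square_km, 3, cfg_a)
        res_b = run_null_model(observed_set, unit_square_km, 3, cfg_b)
        assert np.array_equal(res_a.null_values, res_b.null_values)

    def test_enlarging_polygon_never_decreases_counts(self, observed_set):
        """Under a shared random stream, a superset polygon dominates."""
        small = FarmPolygon([(-500, -500), (500, -500), (500, 500), (-500, 500)])
        big = FarmPolygon([(-2000, -2000), (2000, -2000), (2000, 2000), (-2000, 2000)])
        from windtraj.nullmodels import _replicate_counts

        spec = NullModelSpec.from_id(1)
        sim = simulate_replicates(
            spec, observed_set.coords(), DetectionDisk(), rng_for_model(3, 1), 100
        )
        c_small = _replicate_counts(sim, small, False)
        c_big = _replicate_counts(sim, big, False)
        assert np.all(c_big >= c_small)

    def test_observed_denominator_option(self, observed_set, unit_square_km):
        cfg = RunConfig(
            replicates=100, seed=5, models=(1,), per_replicate_denominator=False
        )
        res = run_null_model(observed_set, unit_square_km, 1, cfg)
        counts = res.null_values * observed_set.total_length_km
        assert np.allclose(counts, np.round(counts))


class TestRunConfig:
    def test_model5_requires_directional_season(self):
        cfg = RunConfig(models=(1, 5))
        with pytest.raises(ValidationError, match="directional"):
            cfg.validate_for_season("spring")
        cfg.validate_for_season("fall")  # allowed

    def test_model5_override(self):
        cfg = RunConfig(models=(5,), allow_model5=True)
        cfg.validate_for_season("spring")

    def test_invalid_parameters(self):
        with pytest.raises(ValidationError):
            RunConfig(replicates=0)
        with pytest.raises(ValidationError):
            RunConfig(alpha=1.5)
        with pytest.raises(ValidationError):
            RunConfig(models=(0, 1))
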