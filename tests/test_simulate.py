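"""Synthetic-herd generator: determinism, moments, mechanism arithmetic."""

import numpy as np
import pandas as pd
import pytest

from herdstress.ethogram import compute_time_budget
from herdstress.hrv import rmssd
from herdstress.simulate import (ArtifactSpec, CohortSpec, SimulationError,
                                 VarianceSpec, gen_behavior_log, gen_cohort,
                                 gen_cortisol, gen_ibi, gen_records,
                                 gen_robot_distance, inject_artifacts,
                                 simulate_study, stress_preset)
from herdstress.config import RunConfig


class TestCohort:
    def test_zero_sds_reproduce_period_means_exactly(self):
        spec = CohortSpec(variances={
            r: VarianceSpec(0, 0, 0, 0) for r in CohortSpec().period_means})
        cohort = gen_cohort(spec, seed=1)
        for (_, _, period, resp), grp in cohort.groupby(
                ["farm", "cow", "period", "response"]):
            assert grp["latent"].iloc[0] == spec.period_means[resp][period]

    def test_negative_sd_rejected(self):
        with pytest.raises(SimulationError):
            VarianceSpec(-1.0, 0, 0)

    def test_seed_determinism(self):
        a = gen_cohort(CohortSpec(), seed=5)
        b = gen_cohort(CohortSpec(), seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_farm_effect_sd_recovered_monte_carlo(self):
        """Empirical farm-effect sd over 10,000 replicate cohorts
        matches the spec within 2%."""
        spec = CohortSpec(
            cows_per_farm=1,
            period_means={"rmssd_a": {p: 100.0 for p in ("B", "T1", "T2", "T3")}},
            variances={"rmssd_a": VarianceSpec(farm_sd=2.0, cow_sd=0.0,
                                               cow_period_sd=0.0, day_cv=0.0)})
        rng = np.random.default_rng(11)
        effects = []
        for _ in range(10_000):
            cohort = gen_cohort(spec, rng)
            per_farm = cohort.groupby("farm")["latent"].first() - 100.0
            effects.extend(per_farm.to_numpy())
        assert np.std(effects) == pytest.approx(2.0, rel=0.02)

    def test_oversized_behavior_means_rejected(self):
        means = {"lying": {p: 700.0 for p in ("B", "T1", "T2", "T3")},
                 "feeding": {p: 200.0 for p in ("B", "T1", "T2", "T3")}}
        with pytest.raises(SimulationError):
            CohortSpec(period_means=means)


class TestIBIGenerator:
    def test_long_run_rmssd_matches_target(self):
        """Law of large numbers: 1e6 intervals recover the target
        RMSSD within 1% (target set to the baseline active-state mean)."""
        s = gen_ibi(6.83, 750.0, 751 * 1000, seed=2)  # ~1e6 intervals
        assert len(s) >= 1_000_000
        assert rmssd(s.intervals) == pytest.approx(6.83, rel=0.01)

    def test_vanishing_variability_limit(self):
        s = gen_ibi(1e-6, 800.0, 400, seed=3)
        assert rmssd(s.intervals) < 1e-5
        assert np.allclose(s.intervals, 800.0)

    def test_duration_reached_and_bounds(self):
        s = gen_ibi(10.0, 800.0, 600, seed=4)
        assert s.duration_s >= 600
        assert s.intervals.min() > 400 and s.intervals.max() < 1200

    def test_invalid_parameters(self):
        with pytest.raises(SimulationError):
            gen_ibi(-1, 800, 400, seed=1)
        with pytest.raises(SimulationError):
            gen_ibi(5, 800, 100, seed=1)


class TestArtifacts:
    def test_zero_rates_identity(self, rng):
        s = gen_ibi(8.0, 800, 330, seed=rng)
        zero = ArtifactSpec(0.0, 0.0, 0.0, 0.0)
        cont, truth = inject_artifacts(s, zero, seed=rng)
        np.testing.assert_array_equal(cont.intervals, s.intervals)
        assert truth == []

    def test_missed_beat_is_sum_of_two(self, rng):
        s = gen_ibi(8.0, 800, 330, seed=rng)
        spec = ArtifactSpec(0.0, 0.0, 0.10, 0.0)
        cont, truth = inject_artifacts(s, spec, seed=rng)
        assert truth and all(m == "missed_beat" for _, m in truth)
        assert len(cont) == len(s) - len(truth)
        for idx, _ in truth:
            # a merged interval is far wider than any genuine one
            assert cont.intervals[idx] > 1.9 * 400
        assert cont.duration_ms == pytest.approx(s.duration_ms, rel=1e-12)

    @pytest.mark.parametrize("spec", [ArtifactSpec(), stress_preset()])
    def test_duration_conserved_by_every_mechanism(self, spec, rng):
        for _ in range(10):
            s = gen_ibi(7.0, 780, 330, seed=rng)
            cont, _ = inject_artifacts(s, spec, seed=rng)
            assert cont.duration_ms == pytest.approx(s.duration_ms, rel=1e-12)

    def test_infeasible_contamination_raises(self, rng):
        s = gen_ibi(8.0, 800, 330, seed=rng).with_intervals([800.0] * 20)
        with pytest.raises(SimulationError):
            inject_artifacts(s, ArtifactSpec(0.4, 0.4, 0.4, 0.4), seed=1)

    def test_ground_truth_indices_point_at_modified_intervals(self, rng):
        s = gen_ibi(8.0, 800, 330, seed=rng)
        cont, truth = inject_artifacts(s, stress_preset(), seed=rng)
        assert truth
        for idx, mech in truth:
            assert 0 <= idx < len(cont)


class TestBehaviorLog:
    def test_single_behavior_fills_all_windows(self, rng):
        ev = gen_behavior_log({"lying": 840.0}, None, rng)
        tb = compute_time_budget(ev)
        assert tb.lying == pytest.approx(840.0)
        assert set(ev["behavior"]) == {"lying"}

    def test_occupancies_partition_the_observed_day(self, rng):
        for _ in range(20):
            ev = gen_behavior_log({"lying": 300.0, "feeding": 120.0,
                                   "locomotion": 100.0}, None, rng)
            tb = compute_time_budget(ev)
            assert tb.observed_minutes == pytest.approx(840.0, abs=1e-6)

    def test_budget_above_observable_day_rejected(self, rng):
        with pytest.raises(SimulationError):
            gen_behavior_log({"lying": 900.0}, None, rng)

    def test_events_fall_inside_observation_windows(self, rng):
        ev = gen_behavior_log({"lying": 400.0, "feeding": 200.0}, None, rng)
        minutes = (ev["start"] - ev["start"].dt.normalize()).dt.total_seconds() / 60
        ok = ((minutes < 240) | ((minutes >= 600) & (minutes < 900))
              | (minutes >= 1140))
        assert ok.all()


class TestRobotDistance:
    def test_cow_on_path_reaches_zero(self):
        dist = gen_robot_distance(None, 4.0, seed=1, cow_pos=(5.0, 0.0))
        assert dist["distance_m"].min() == pytest.approx(0.0, abs=0.1)

    def test_pass_duration_is_perimeter_over_speed(self):
        # 40 m loop at 4 m/min -> 10 min per pass at 1-s sampling
        dist = gen_robot_distance(None, 4.0, seed=2, pen=(10.0, 10.0))
        counts = dist.groupby("pass_id").size()
        # 1-s sampling of a continuous boundary: 600 samples up to rounding
        assert counts.iloc[:-1].sub(600).abs().max() <= 1

    def test_speed_must_be_positive(self):
        with pytest.raises(SimulationError):
            gen_robot_distance(None, 0.0, seed=1)


class TestCortisol:
    def test_cv_zero_gives_constant_samples(self):
        vals = gen_cortisol(15.36, 0.0, seed=1, n_samples=5)
        np.testing.assert_allclose(vals, 15.36)

    def test_samples_positive_and_median_centred(self):
        vals = gen_cortisol(15.36, 0.2, seed=2, n_samples=20_000)
        assert (vals > 0).all()
        assert np.median(vals) == pytest.approx(15.36, rel=0.02)

    def test_invalid_latent(self):
        with pytest.raises(SimulationError):
            gen_cortisol(-1.0, 0.2, seed=1)


def test_study_is_pure_function_of_seed():
    cfg = RunConfig(n_farms=1, n_cows_per_farm=2)
    a = simulate_study(cfg, seed=42, with_distance=False, with_ibi=False)
    b = simulate_study(cfg, seed=42, with_distance=False, with_ibi=False)
    pd.testing.assert_frame_equal(a["cohort"], b["cohort"])
    pd.testing.assert_frame_equal(a["behavior"], b["behavior"])
    pd.testing.assert_frame_equal(a["cortisol"], b["cortisol"])
    c = simulate_study(cfg, seed=43, with_distance=False, with_ibi=False)
    assert not a["cortisol"]["concentration"].equals(c["cortisol"]["concentration"])


def test_records_have_day_replication(rng):
    cohort = gen_cohort(CohortSpec(n_farms=1, cows_per_farm=3), seed=6)
    rec = gen_records(cohort, "cortisol", days=(2, 3, 5), seed=7)
    assert len(rec) == 3 * 4 * 3
    assert (rec["value"] > 0).all()
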