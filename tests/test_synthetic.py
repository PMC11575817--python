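"""Cohort, trajectory and device-model generators."""

import numpy as np
import pytest

from vbtval.dataset import EXERCISES
from vbtval.kinematics import differentiate
from vbtval.synthetic import (DEFAULT_TABLE1, DEFAULT_TRAJECTORIES,
                              DeviceProfile, ProtocolSpec, Subject,
                              Table1Params, TrajectoryConfig, TruncatedNormal,
                              TrueRep, protocol_loads, simulate_cohort,
                              simulate_device, simulate_trajectory,
                              target_mean_velocity)


class TestCohort:
    def test_absolute_1rm_means_lie_in_published_ranges(self):
        cohort = simulate_cohort(20, seed=1)
        ranges = {"squat": (120, 310), "bench": (55, 230), "deadlift": (142.5, 360)}
        for ex, (lo, hi) in ranges.items():
            mean_rm = np.mean([s.one_rm[ex] for s in cohort])
            assert lo <= mean_rm <= hi
        for s in cohort:
            assert 55.8 <= s.body_mass <= 147.7
            assert 1.68 <= s.one_rm["squat"] / s.body_mass <= 3.46

    def test_zero_sd_collapses_to_published_means(self):
        params = Table1Params(
            body_mass=TruncatedNormal(83.4, 0.0, 55.8, 147.7),
            relative_one_rm={
                "squat": TruncatedNormal(2.32, 0.0, 1.68, 3.46),
                "bench": TruncatedNormal(1.46, 0.0, 0.88, 2.28),
                "deadlift": TruncatedNormal(2.71, 0.0, 2.07, 3.88)})
        (subj,) = simulate_cohort(1, seed=0, table1_params=params)
        assert subj.body_mass == pytest.approx(83.4)
        assert subj.one_rm["squat"] == pytest.approx(2.32 * 83.4)

    def test_same_seed_same_cohort(self):
        assert simulate_cohort(10, seed=7) == simulate_cohort(10, seed=7)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError, match="sd"):
            TruncatedNormal(80.0, -1.0, 50.0, 150.0)


class TestProtocolLoads:
    @pytest.mark.parametrize("one_rm,fraction,expected", [
        (200.0, 0.45, 90.0),     # exact multiple of 2.5
        (193.0, 0.45, 87.5),     # 86.85 -> nearest multiple (brute-force checked)
        (205.0, 0.45, 92.5),     # 92.25 -> 92.5
    ])
    def test_rounding_to_nearest_increment(self, one_rm, fraction, expected):
        subj = Subject("S01", 80.0, {"squat": one_rm, "bench": 100, "deadlift": 200})
        spec = ProtocolSpec(load_fractions=(fraction,))
        assert protocol_loads(subj, "squat", spec) == [expected]

    def test_rounding_matches_brute_force(self):
        subj = Subject("S01", 80.0, {"squat": 193.0, "bench": 100, "deadlift": 200})
        loads = protocol_loads(subj, "squat")
        for f, load in zip(ProtocolSpec().load_fractions, loads):
            raw = f * 193.0
            candidates = np.arange(0, 400, 2.5)
            best = candidates[np.argmin(np.abs(candidates - raw))]
            # ties round up
            ties = candidates[np.isclose(np.abs(candidates - raw),
                                         np.min(np.abs(candidates - raw)))]
            assert load == max(ties) if len(ties) > 1 else load == best

    def test_default_ladder_has_ten_loads(self):
        subj = Subject("S01", 80.0, {"squat": 187.3, "bench": 100, "deadlift": 200})
        assert len(protocol_loads(subj, "squat")) == 10

    def test_unknown_exercise_rejected(self):
        subj = Subject("S01", 80.0, {"squat": 100.0})
        with pytest.raises(KeyError):
            protocol_loads(subj, "bench")


class TestTrajectory:
    def test_noiseless_concentric_matches_closed_form(self):
        cfg = TrajectoryConfig("squat", rom=0.5, mv_at_min_load=0.5001,
                               mv_at_max_load=0.25)
        traj, true_mv = simulate_trajectory("squat", 0.45, cfg, seed=0)
        # target MV at the lightest load is the min-load anchor
        assert true_mv == pytest.approx(0.5001, rel=5e-3)
        z = traj.vertical
        assert np.ptp(z) == pytest.approx(0.5, abs=1e-9)
        # concentric phase spans bottom to top in rom/true_mv seconds
        n_con = round(0.5 / true_mv * 200)
        i_bottom = int(np.argmin(z))
        seg = z[i_bottom:i_bottom + n_con + 1]
        disp = seg[-1] - seg[0]
        assert disp / (n_con / 200.0) == pytest.approx(true_mv, abs=1e-6)

    @pytest.mark.parametrize("exercise", EXERCISES)
    def test_phase_order(self, exercise):
        from dataclasses import replace
        cfg = replace(DEFAULT_TRAJECTORIES[exercise], noise_sd=0.0)
        traj, _ = simulate_trajectory(exercise, 0.60, cfg, seed=0)
        z = traj.vertical
        i_min, i_max = int(np.argmin(z)), int(np.argmax(z))
        if exercise == "deadlift":
            assert z[0] == pytest.approx(z.min(), abs=1e-9)  # starts on the floor
            assert i_max > 0.1 * z.size
        else:
            assert z[0] == pytest.approx(z.max(), abs=1e-9)  # starts racked high
            assert i_min > 0.1 * z.size

    def test_sticking_dip_depth_and_conserved_displacement(self):
        cfg = TrajectoryConfig("squat", rom=0.5, mv_at_min_load=0.5,
                               mv_at_max_load=0.25, sticking_dip_depth=0.5)
        traj, true_mv = simulate_trajectory("squat", 0.45, cfg, seed=0)
        assert np.ptp(traj.vertical) == pytest.approx(0.5, abs=1e-6)
        v = differentiate(traj)
        z = traj.vertical
        i_bottom = int(np.argmin(z))
        i_top = i_bottom + int(np.argmax(z[i_bottom:]))
        vcon = v[i_bottom:i_top + 1]
        i_pk1 = int(np.argmax(vcon[: vcon.size // 2]))
        i_pk2 = vcon.size // 2 + int(np.argmax(vcon[vcon.size // 2:]))
        v_min_between = vcon[i_pk1:i_pk2 + 1].min()
        v_peak = vcon.max()
        assert v_min_between / v_peak == pytest.approx(0.5, abs=0.06)

    def test_bench_pause_is_quiet(self):
        cfg = TrajectoryConfig("bench", rom=0.4, mv_at_min_load=0.75,
                               mv_at_max_load=0.17, pause_duration=1.0)
        traj, _ = simulate_trajectory("bench", 0.60, cfg, seed=0)
        v = differentiate(traj)
        quiet = np.abs(v) < 0.02
        # longest quiet run strictly between the two moving phases
        moving = np.where(~quiet)[0]
        gaps = np.diff(moving)
        assert gaps.max() / 200.0 >= 0.9

    def test_determinism_and_noise(self):
        cfg = TrajectoryConfig("squat", rom=0.5, mv_at_min_load=0.5,
                               mv_at_max_load=0.25, noise_sd=0.001)
        t1, _ = simulate_trajectory("squat", 0.6, cfg, seed=5)
        t2, _ = simulate_trajectory("squat", 0.6, cfg, seed=5)
        t3, _ = simulate_trajectory("squat", 0.6, cfg, seed=6)
        assert np.array_equal(t1.position, t2.position)
        assert not np.array_equal(t1.position, t3.position)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="rom"):
            TrajectoryConfig("squat", rom=0.08, mv_at_min_load=0.5, mv_at_max_load=0.2)
        with pytest.raises(ValueError, match="decrease"):
            TrajectoryConfig("squat", rom=0.5, mv_at_min_load=0.2, mv_at_max_load=0.5)
        with pytest.raises(ValueError, match="dip"):
            TrajectoryConfig("squat", rom=0.5, mv_at_min_load=0.5,
                             mv_at_max_load=0.2, sticking_dip_depth=1.0)

    def test_load_velocity_mapping_spans_study_range(self):
        mvs = [target_mean_velocity(f, DEFAULT_TRAJECTORIES[ex])
               for ex in EXERCISES
               for f in np.linspace(0.45, 0.90, 10)]
        assert 0.1 < min(mvs) < 0.25
        assert 0.7 < max(mvs) <= 1.05


def _true_reps(n, seed=0, mv_low=0.1, mv_high=1.0, n_subjects=20):
    rng = np.random.default_rng(seed)
    reps = []
    for k in range(n):
        reps.append(TrueRep(f"S{k % n_subjects:02d}", "squat", 50.0, k // n_subjects + 1,
                            1, float(rng.uniform(mv_low, mv_high))))
    return reps


class TestDeviceModel:
    def test_identity_device_reproduces_truth(self):
        reps = _true_reps(100)
        obs = simulate_device(reps, DeviceProfile("dev"), seed=1)
        assert all(o.status == "ok" for o in obs)
        assert np.allclose([o.mean_velocity for o in obs],
                           [r.mean_velocity for r in reps])

    def test_fixed_bias_is_exact_without_noise(self):
        reps = _true_reps(1000)
        obs = simulate_device(reps, DeviceProfile("dev", alpha=0.05), seed=1)
        diffs = np.array([o.mean_velocity - r.mean_velocity
                          for o, r in zip(obs, reps)])
        assert diffs == pytest.approx(0.05)

    def test_all_missed_when_miss_prob_one(self):
        obs = simulate_device(_true_reps(50), DeviceProfile("dev", miss_prob=1.0), seed=1)
        assert all(o.status == "missed" and o.mean_velocity is None for o in obs)

    def test_missed_rate_matches_probability(self):
        n, p = 20000, 0.08
        obs = simulate_device(_true_reps(n), DeviceProfile("dev", miss_prob=p), seed=3)
        rate = np.mean([o.status == "missed" for o in obs])
        assert abs(rate - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_bias_injection_recovered_by_ols(self):
        n = 20000
        reps = _true_reps(n, seed=2)
        prof = DeviceProfile("dev", alpha=0.04, beta=0.92, sigma=0.05)
        obs = simulate_device(reps, prof, seed=4)
        x = np.array([r.mean_velocity for r in reps])
        y = np.array([o.mean_velocity for o in obs])
        X = np.column_stack([np.ones_like(x), x])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        se = np.sqrt(np.sum(resid ** 2) / (n - 2) * np.linalg.inv(X.T @ X).diagonal())
        assert abs(coef[0] - 0.04) < 3 * se[0]
        assert abs(coef[1] - 0.92) < 3 * se[1]

    def test_ghosts_are_marked_and_appended(self):
        reps = _true_reps(200, n_subjects=10)
        obs = simulate_device(reps, DeviceProfile("dev", ghost_prob=1.0), seed=1)
        ghosts = [o for o in obs if o.status == "ghost"]
        n_sets = len({(r.subject_id, r.exercise, r.load_pct, r.set_index) for r in reps})
        assert len(ghosts) == n_sets
        assert all(0 < g.mean_velocity < 0.15 for g in ghosts)

    def test_random_effects_shared_within_subject(self):
        reps = _true_reps(400, n_subjects=4)
        prof = DeviceProfile("dev", re_cov=((0.05 ** 2, 0.0), (0.0, 0.0)))
        obs = simulate_device(reps, prof, seed=9)
        # per-subject mean offset should differ between subjects but each
        # subject's offsets are constant (sigma = 0)
        offsets = {}
        for o, r in zip(obs, reps):
            offsets.setdefault(o.subject_id, set()).add(
                round(o.mean_velocity - r.mean_velocity, 12))
        assert all(len(v) == 1 for v in offsets.values())
        assert len({next(iter(v)) for v in offsets.values()}) > 1

    def test_device_determinism(self):
        reps = _true_reps(100)
        prof = DeviceProfile("dev", sigma=0.05, miss_prob=0.1, ghost_prob=0.1)
        assert simulate_device(reps, prof, seed=5) == simulate_device(reps, prof, seed=5)
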