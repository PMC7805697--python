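import math

import numpy as np
import pytest

import oracles
from ethotank.arena import make_default_arena
from ethotank.metrics import (MetricOptions, avoidance_rate, avoidance_score,
                              compute_metrics, door_time_metrics,
                              freezing_time, heading_error, kinematics,
                              metrics_table, modified_preference,
                              trajectory_entropy, wall_metrics)
from ethotank.records import TrialRecord, Trajectory


def make_record(xy, dt=0.05, correct_door="lower", T=None, censored=None,
                time_limit=1e9, interpolated=None):
    traj = Trajectory.from_positions(np.asarray(xy, float), dt=dt)
    if interpolated is not None:
        traj.interpolated = np.asarray(interpolated, bool)
    return TrialRecord(subject_traj=traj, correct_door=correct_door, T=T,
                       censored=censored, time_limit_s=time_limit)


class TestDoorTimeMetrics:
    def test_equal_times_give_half(self, arena):
        # 40 samples in each zone
        xy = np.vstack([np.tile([27.0, 7.5], (40, 1)),
                        np.tile([27.0, 22.5], (40, 1))])
        rec = make_record(xy)
        tau_c, tau_i, pi = door_time_metrics(rec, arena)
        assert tau_c == pytest.approx(tau_i)
        assert pi == pytest.approx(0.5)

    def test_formula_75_percent(self, arena):
        xy = np.vstack([np.tile([27.0, 7.5], (600, 1)),     # 30 s correct
                        np.tile([27.0, 22.5], (200, 1))])   # 10 s incorrect
        rec = make_record(xy)
        tau_c, tau_i, pi = door_time_metrics(rec, arena)
        assert tau_c == pytest.approx(30.0)
        assert tau_i == pytest.approx(10.0)
        assert pi == pytest.approx(0.75)

    def test_undefined_when_never_near_doors(self, arena):
        rec = make_record(np.tile([5.0, 15.0], (100, 1)))
        *_, pi = door_time_metrics(rec, arena)
        assert pi is None

    def test_truncated_at_door_opening(self, arena):
        xy = np.vstack([np.tile([27.0, 7.5], (100, 1)),
                        np.tile([27.0, 22.5], (100, 1))])
        rec = make_record(xy, T=5.0, censored=False)
        tau_c, tau_i, _ = door_time_metrics(rec, arena)
        # samples t=0..4.95 are at the correct door; the boundary sample at
        # t=5.0 (inclusive) is the first one at the incorrect door
        assert tau_c == pytest.approx(5.0)
        assert tau_i == pytest.approx(0.05)

    def test_matches_oracle_on_random_walks(self, arena, focal_traj_factory):
        for _ in range(20):
            traj = focal_traj_factory(n=250, step_sd=2.5)
            rec = TrialRecord(subject_traj=traj, correct_door="lower",
                              time_limit_s=1e9)
            got = door_time_metrics(rec, arena)
            want = oracles.door_times(traj, arena, "lower", t_end=1e9)
            assert got[0] == pytest.approx(want[0])
            assert got[1] == pytest.approx(want[1])


class TestWallMetrics:
    def test_equal_wall_times_quarter(self, arena):
        xy = np.vstack([np.tile([29.0, 15.0], (50, 1)),   # wall 1
                        np.tile([15.0, 1.0], (50, 1)),    # wall 2
                        np.tile([1.0, 15.0], (50, 1)),    # wall 3
                        np.tile([15.0, 29.0], (50, 1))])  # wall 4
        rec = make_record(xy)
        times, ri = wall_metrics(rec, arena)
        assert ri == pytest.approx(0.25)
        assert all(t == pytest.approx(2.5) for t in times)

    def test_all_time_at_partition_gives_one(self, arena):
        rec = make_record(np.tile([29.0, 15.0], (100, 1)))
        _, ri = wall_metrics(rec, arena)
        assert ri == pytest.approx(1.0)

    def test_undefined_without_wall_time(self, arena):
        rec = make_record(np.tile([15.0, 15.0], (100, 1)))
        times, ri = wall_metrics(rec, arena)
        assert ri is None
        assert sum(times) == 0.0

    def test_matches_oracle(self, arena, focal_traj_factory):
        for _ in range(20):
            traj = focal_traj_factory(n=250, step_sd=3.0)
            rec = TrialRecord(subject_traj=traj, time_limit_s=1e9)
            times, ri = wall_metrics(rec, arena)
            w_times, w_ri = oracles.wall_times(traj, arena, t_end=1e9)
            assert times == pytest.approx(w_times)
            assert (ri is None) == (w_ri is None)
            if ri is not None:
                assert ri == pytest.approx(w_ri)


class TestEntropy:
    def test_single_bin_zero(self, arena):
        rec = make_record(np.tile([15.1, 15.1], (100, 1)))
        assert trajectory_entropy(rec, arena) == pytest.approx(0.0)

    def test_two_equal_bins_one_bit(self, arena):
        xy = np.vstack([np.tile([1.5, 1.5], (50, 1)),
                        np.tile([28.5, 28.5], (50, 1))])
        rec = make_record(xy)
        assert trajectory_entropy(rec, arena) == pytest.approx(1.0)

    def test_uniform_maximum(self, arena):
        centers = [1.5 + 3.0 * i for i in range(10)]
        xy = np.array([(x, y) for x in centers for y in centers])
        rec = make_record(xy)
        h = trajectory_entropy(rec, arena)
        assert h == pytest.approx(math.log2(100))

    def test_bounds_on_random_walks(self, arena, focal_traj_factory):
        for _ in range(10):
            rec = TrialRecord(subject_traj=focal_traj_factory(n=300),
                              time_limit_s=1e9)
            h = trajectory_entropy(rec, arena)
            assert 0.0 <= h <= math.log2(100) + 1e-12

    def test_matches_oracle(self, arena, focal_traj_factory):
        for _ in range(10):
            traj = focal_traj_factory(n=200, step_sd=2.0)
            rec = TrialRecord(subject_traj=traj, time_limit_s=1e9)
            assert trajectory_entropy(rec, arena) == pytest.approx(
                oracles.entropy_bits(traj, arena, t_end=1e9))


class TestHeadingError:
    def test_straight_at_door_zero(self, arena):
        # swim from (20,7.5) straight toward the lower door at (30,7.5)
        x = np.linspace(20.0, 25.0, 50)
        xy = np.column_stack([x, np.full(50, 7.5)])
        _, mean = heading_error(make_record(xy), arena)
        assert mean == pytest.approx(0.0, abs=1e-9)

    def test_straight_away_180(self, arena):
        x = np.linspace(25.0, 20.0, 50)
        xy = np.column_stack([x, np.full(50, 7.5)])
        _, mean = heading_error(make_record(xy), arena)
        assert mean == pytest.approx(180.0)

    def test_slow_samples_excluded(self, arena):
        xy = np.tile([15.0, 15.0], (50, 1))  # never moves
        _, mean = heading_error(make_record(xy), arena)
        assert mean is None

    def test_matches_vector_math_oracle(self, arena, focal_traj_factory):
        for _ in range(20):
            traj = focal_traj_factory(n=200, step_sd=1.5, with_flags=True)
            rec = TrialRecord(subject_traj=traj, correct_door="upper",
                              time_limit_s=1e9)
            _, mean = heading_error(rec, arena)
            want = oracles.heading_mean_deg(traj, arena, "upper", t_end=1e9)
            if want is None:
                assert mean is None
            else:
                assert mean == pytest.approx(want)


class TestKinematics:
    def test_speed_formula(self, arena):
        xy = np.column_stack([np.arange(10) * 1.0, np.zeros(10)])
        v, _, _ = kinematics(make_record(xy + [5.0, 15.0]))
        assert v == pytest.approx(20.0)  # 1 cm per 0.05 s

    def test_quarter_turn_rate(self, arena):
        dt = 0.05
        xy = np.array([[0.0, 0.0], [1.0 * dt, 0.0], [1.0 * dt, 1.0 * dt]])
        _, _, w = kinematics(make_record(xy + [15.0, 15.0]))
        assert w == pytest.approx((math.pi / 2) / dt)

    def test_constant_velocity_zero_accel_turn(self, arena):
        xy = np.column_stack([np.arange(50) * 0.3, np.arange(50) * 0.1])
        v, a, w = kinematics(make_record(xy + [2.0, 2.0]))
        assert a == pytest.approx(0.0, abs=1e-9)
        assert w == pytest.approx(0.0, abs=1e-6)

    def test_matches_oracle(self, arena, focal_traj_factory):
        for _ in range(20):
            traj = focal_traj_factory(n=150, step_sd=1.0, with_flags=True)
            rec = TrialRecord(subject_traj=traj, time_limit_s=1e9)
            got = kinematics(rec)
            want = oracles.kinematics_means(traj, t_end=1e9)
            for g, w in zip(got, want):
                if w is None:
                    assert g is None
                else:
                    assert g == pytest.approx(w)


class TestFreezing:
    def test_fully_stationary(self, arena):
        rec = make_record(np.tile([15.0, 15.0], (200, 1)))  # 10 s
        assert freezing_time(rec) == pytest.approx(10.0)

    def test_steady_swim_never_frozen(self, arena):
        # 5 cm/s -> 10 cm per 2 s window, 5 cm per clipped edge window
        n = 200
        xy = np.column_stack([2.0 + 0.25 * np.arange(n), np.full(n, 15.0)])
        rec = make_record(xy)
        assert freezing_time(rec) == pytest.approx(0.0)

    def test_stop_and_go_matches_oracle(self, arena):
        rng = np.random.default_rng(7)
        pieces = []
        pos = np.array([10.0, 10.0])
        for _ in range(6):
            hold = np.tile(pos, (int(rng.integers(10, 60)), 1))
            pieces.append(hold)
            step = rng.uniform(-0.4, 0.4, size=(int(rng.integers(10, 50)), 2))
            walk = pos + np.cumsum(step, axis=0)
            walk = np.clip(walk, 0.5, 29.5)
            pieces.append(walk)
            pos = walk[-1]
        traj = Trajectory.from_positions(np.vstack(pieces))
        rec = TrialRecord(subject_traj=traj, time_limit_s=1e9)
        assert freezing_time(rec) == pytest.approx(
            oracles.freezing_seconds(traj, t_end=1e9))

    def test_path_mode_differs_for_jitter(self, arena):
        # rapid jitter in place: near-zero net movement, large path length
        rng = np.random.default_rng(1)
        ang = rng.uniform(0, 2 * np.pi, 200)
        xy = np.array([15.0, 15.0]) + np.column_stack(
            [np.cos(ang), np.sin(ang)])
        rec = make_record(xy)
        net = freezing_time(rec, MetricOptions(freezing_mode="net"))
        path = freezing_time(rec, MetricOptions(freezing_mode="path"))
        assert net > path


class TestAvoidance:
    def _record_with_opening(self, retreat_to, arena):
        pre = np.tile([27.0, 7.5], (61, 1))          # trigger at 3.0 s
        post = np.tile(retreat_to, (300, 1))
        return make_record(np.vstack([pre, post]), T=3.0, censored=False)

    def test_retreat_beyond_two_bl(self, arena):
        rec = self._record_with_opening([23.0, 7.5], arena)  # 7 cm away
        assert avoidance_score(rec, arena) is True

    def test_stays_close(self, arena):
        rec = self._record_with_opening([26.0, 7.5], arena)  # 4 cm away
        assert avoidance_score(rec, arena) is False

    def test_censored_undefined(self, arena):
        rec = make_record(np.tile([5.0, 15.0], (100, 1)), T=1800.0,
                          censored=True)
        assert avoidance_score(rec, arena) is None

    def test_avoidance_rate(self):
        flags = [True] * 58 + [False] * 14
        assert avoidance_rate(flags) == pytest.approx(80.6, abs=0.05)
        assert avoidance_rate([None, True]) == pytest.approx(100.0)
        assert avoidance_rate([None]) is None


class TestModifiedPreference:
    def test_all_middle(self, arena):
        rec = make_record(np.tile([15.0, 15.0], (100, 1)))
        assert modified_preference(rec, arena) == pytest.approx(1.0)

    def test_uniform_third(self, arena):
        y = np.linspace(0.05, 29.95, 300)
        xy = np.column_stack([np.full(300, 15.0), y])
        rec = make_record(xy)
        assert modified_preference(rec, arena) == pytest.approx(1 / 3, abs=0.01)

    def test_matches_oracle(self, arena, focal_traj_factory):
        for _ in range(10):
            traj = focal_traj_factory(n=200, step_sd=2.0)
            rec = TrialRecord(subject_traj=traj, time_limit_s=1e9)
            assert modified_preference(rec, arena) == pytest.approx(
                oracles.middle_third_fraction(traj, t_end=1e9))


class TestInvariants:
    def test_fractions_in_unit_interval(self, arena, focal_traj_factory):
        for _ in range(10):
            rec = TrialRecord(subject_traj=focal_traj_factory(n=200),
                              time_limit_s=1e9)
            m = compute_metrics(rec, arena)
            for val in (m.PI, m.RI, m.PI_m):
                if val is not None:
                    assert 0.0 <= val <= 1.0
            assert 0.0 <= m.F <= rec.subject_traj.duration + 0.05 + 1e-9

    def test_reflection_symmetry(self, arena, focal_traj_factory):
        # mirror across mid-width + door relabel leaves measures unchanged
        for _ in range(5):
            traj = focal_traj_factory(n=300, step_sd=2.0)
            rec = TrialRecord(subject_traj=traj, correct_door="lower",
                              time_limit_s=1e9)
            mirrored = Trajectory(traj.t, np.column_stack(
                [traj.xy[:, 0], 30.0 - traj.xy[:, 1]]),
                traj.valid, traj.interpolated)
            rec_m = TrialRecord(subject_traj=mirrored, correct_door="upper",
                                time_limit_s=1e9)
            a = compute_metrics(rec, arena)
            b = compute_metrics(rec_m, arena)
            assert a.tau_C == pytest.approx(b.tau_C)
            assert a.tau_I == pytest.approx(b.tau_I)
            assert a.H == pytest.approx(b.H)
            assert a.PI_m == pytest.approx(b.PI_m)
            assert a.F == pytest.approx(b.F)
            if a.theta_C_mean is not None:
                assert a.theta_C_mean == pytest.approx(b.theta_C_mean)
            if a.RI is not None:
                assert a.RI == pytest.approx(b.RI)

    def test_metrics_table_emits_empty_for_undefined(self, arena, tmp_path):
        rec = TrialRecord(
            subject_traj=Trajectory.from_positions(
                np.tile([15.0, 15.0], (50, 1))),
            time_limit_s=1e9)
        table = metrics_table([rec], arena)
        path = tmp_path / "m.csv"
        table.to_csv(path, index=False)
        import pandas as pd

        back = pd.read_csv(path)
        assert back["PI"].isna().all()       # undefined, not zero
        assert back["F"].iloc[0] > 0
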