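import numpy as np
import pytest

from flyddm import (
    ChamberGeometry,
    CrossingSpec,
    Trajectory,
    extract_decisions,
    normalize_rt,
    process_trajectory,
    qc_trajectory,
    simulate_trajectory,
    smooth_positions,
)
from flyddm.errors import ValidationError
from flyddm.kinematics import count_runs, offcenter_transits

GEOM = ChamberGeometry()


class TestSmoothing:
    def test_constant_unchanged(self):
        x = np.full(40, 12.3)
        np.testing.assert_allclose(smooth_positions(x, 10), x)

    def test_window_one_identity(self):
        x = np.arange(15.0)
        np.testing.assert_array_equal(smooth_positions(x, 1), x)

    def test_length_preserved(self):
        assert smooth_positions(np.arange(25.0), 10).size == 25

    def test_step_becomes_ramp(self):
        x = np.concatenate([np.zeros(20), np.full(20, 10.0)])
        s = smooth_positions(x, 10)
        ramp = s[(s > 0.5) & (s < 9.5)]
        assert 5 <= ramp.size <= 10  # spread over about one window
        assert np.all(np.diff(s) >= 0)

    def test_too_short_sequence(self):
        with pytest.raises(ValidationError):
            smooth_positions(np.arange(5.0), 10)


def _manual_crossing(entry_frame=30, dwell_frames=45, inside_fraction=0.01,
                     approach_speed=0.5, exit_side="right"):
    """Hand-built unsmoothed trajectory: approach at `approach_speed` mm/frame,
    crawl inside at `inside_fraction` of it, leave at full speed."""
    lo, hi = GEOM.zone_lo, GEOM.zone_hi
    pos = [lo - (entry_frame - i) * approach_speed for i in range(entry_frame)]
    crawl = inside_fraction * approach_speed
    pos += [lo + 0.05 + crawl * j for j in range(dwell_frames)]
    out_start = hi + 0.05 if exit_side == "right" else lo - 0.05
    sign = 1.0 if exit_side == "right" else -1.0
    pos += [out_start + sign * approach_speed * j for j in range(40)]
    return Trajectory(positions=np.clip(pos, 0, GEOM.length - 1e-6), low_conc_side="right")


class TestExtraction:
    def test_recovers_dwell_time(self):
        traj = _manual_crossing(entry_frame=30, dwell_frames=45)
        events = extract_decisions(traj, GEOM)
        ev = [e for e in events if e.entry_frame == 30][0]
        assert ev.valid and ev.reason == "ok"
        assert ev.rt_raw == pytest.approx(45 / 30.0)
        assert ev.choice == 1  # exited right = low-concentration arm

    def test_timeout_rejected(self):
        traj = _manual_crossing(dwell_frames=16 * 30 + 1)
        ev = extract_decisions(traj, GEOM)[0]
        assert not ev.valid and ev.reason == "timeout"

    def test_insufficient_slowdown_rejected(self):
        traj = _manual_crossing(inside_fraction=0.5, dwell_frames=20)
        ev = extract_decisions(traj, GEOM)[0]
        assert not ev.valid and ev.reason == "no_slowdown"

    def test_incorrect_choice_sign(self):
        traj = _manual_crossing(exit_side="left")
        ev = extract_decisions(traj, GEOM)[0]
        assert ev.choice == -1

    def test_no_exit_flagged(self):
        lo = GEOM.zone_lo
        pos = list(np.linspace(lo - 10, lo - 0.1, 30)) + [lo + 1.0] * 60
        ev = extract_decisions(Trajectory(positions=pos), GEOM)[-1]
        assert not ev.valid and ev.reason == "no_exit"

    def test_every_event_has_one_reason(self):
        traj = _manual_crossing()
        for ev in extract_decisions(traj, GEOM):
            assert ev.reason in {"ok", "timeout", "no_slowdown", "no_exit"}
            assert ev.valid == (ev.reason == "ok")


class TestQC:
    @staticmethod
    def _runs_trajectory(n_runs):
        mid = GEOM.length / 2.0
        pos = [2.0]
        for _ in range(n_runs):
            pos += list(np.linspace(2.0, mid, 40)) + list(np.linspace(mid, 2.0, 40))
        return Trajectory(positions=pos)

    @pytest.mark.parametrize("runs,accepted", [(0, False), (1, False), (3, True)])
    def test_run_threshold(self, runs, accepted):
        traj = self._runs_trajectory(runs)
        assert qc_trajectory(traj, GEOM).accepted is accepted

    def test_grooming_flag(self):
        traj = self._runs_trajectory(3)
        res = qc_trajectory(traj, GEOM, grooming=True)
        assert not res.accepted and res.reason == "grooming"

    def test_run_counter(self):
        assert count_runs(self._runs_trajectory(4).positions, GEOM) == 4


class TestNormalization:
    def test_ratio(self):
        spec = [CrossingSpec("left", 1.5, 0.95, "right"),
                CrossingSpec("right", 1.2, 0.95, "left")]
        traj = simulate_trajectory(spec, GEOM, base_speed=10.0)
        events = extract_decisions(traj, GEOM)
        transits = offcenter_transits(traj, GEOM)
        assert transits, "trajectory must cross the off-center zones"
        normalized = normalize_rt(events, traj, GEOM)
        for ev in normalized:
            assert ev.rt_normalized == pytest.approx(ev.rt_raw / np.mean(transits), rel=1e-9)

    def test_transit_equal_to_rt_gives_unity(self):
        class _E:
            pass

        from flyddm.kinematics import DecisionEvent

        ev = DecisionEvent(0, 10, 0.7, 1, True, "ok")
        spec = [CrossingSpec("left", 1.5, 0.95, "right")] * 2
        traj = simulate_trajectory(spec, GEOM, base_speed=10.0)
        transit = float(np.mean(offcenter_transits(traj, GEOM)))
        ev = DecisionEvent(0, 10, transit, 1, True, "ok")
        out = normalize_rt([ev], traj, GEOM)[0]
        assert out.rt_normalized == pytest.approx(1.0)

    def test_missing_transits_flagged(self):
        from flyddm.kinematics import DecisionEvent

        # trajectory confined to the decision zone: no off-center transits
        pos = np.full(60, GEOM.length / 2.0)
        ev = DecisionEvent(0, 10, 0.5, 1, True, "ok")
        out = normalize_rt([ev], Trajectory(positions=pos), GEOM)[0]
        assert not out.valid and out.reason == "no_transit"

    def test_time_rescaling_invariance(self):
        # halving walking speed everywhere doubles raw times but leaves
        # normalized reaction times unchanged
        spec = [CrossingSpec("left", 1.5, 0.95, "right"),
                CrossingSpec("right", 1.8, 0.95, "left")]
        fast = simulate_trajectory(spec, GEOM, base_speed=10.0)
        n = fast.positions.size
        slow_pos = np.interp(np.arange(2 * n - 1) / 2.0, np.arange(n), fast.positions)
        slow = Trajectory(positions=slow_pos)
        _, ev_fast = process_trajectory(fast, GEOM)
        _, ev_slow = process_trajectory(slow, GEOM)
        rt_fast = [e.rt_normalized for e in ev_fast if e.valid]
        rt_slow = [e.rt_normalized for e in ev_slow if e.valid]
        assert len(rt_fast) == len(rt_slow) > 0
        np.testing.assert_allclose(rt_fast, rt_slow, rtol=0.08)


class TestSimulatedTrajectories:
    def test_round_trip_dwell(self):
        spec = [CrossingSpec("left", 1.5, 0.95, "right"),
                CrossingSpec("right", 1.5, 0.95, "left")]
        traj = simulate_trajectory(spec, GEOM, base_speed=10.0, jitter_sd=0.0)
        qc, events = process_trajectory(traj, GEOM)
        assert qc.accepted
        valid = [e for e in events if e.valid]
        assert len(valid) == 2
        for ev in valid:
            assert ev.rt_raw == pytest.approx(1.5, abs=1.5 / 30.0)

    def test_weak_slowdown_rejected_round_trip(self):
        spec = [CrossingSpec("left", 1.2, 0.5, "right"),
                CrossingSpec("right", 1.2, 0.5, "left")]
        traj = simulate_trajectory(spec, GEOM)
        _, events = process_trajectory(traj, GEOM)
        assert all(not e.valid for e in events)
        assert any(e.reason == "no_slowdown" for e in events)

    def test_infeasible_dwell_raises(self):
        with pytest.raises(ValidationError):
            simulate_trajectory([CrossingSpec("left", 0.1, 0.95, "right")], GEOM)

    def test_decisions_bounded_by_crossings(self):
        spec = [CrossingSpec("left", 1.5, 0.95, "right")] * 3
        traj = simulate_trajectory(spec, GEOM)
        events = extract_decisions(traj, GEOM)
        in_zone = (traj.positions >= GEOM.zone_lo) & (traj.positions < GEOM.zone_hi)
        crossings = int(np.sum(np.diff(in_zone.astype(int)) == 1) + in_zone[0])
        assert len(events) <= crossings
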