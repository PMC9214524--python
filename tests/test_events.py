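"""Delayed collisions: outcome classification, separatrix, event detection."""

import numpy as np
import pandas as pd
import pytest

from chemotrails import (
    DynamicsParams,
    FieldParams,
    classify_event,
    detect_interactions,
    separatrix,
    simulate_event,
)
from chemotrails.synthetic import gen_event_pair


class TestSimulateEvent:
    def test_no_couplings_crossing_at_constant_speed(self, fp):
        p = DynamicsParams(alpha_c0=0.0, omega_c0=0.0)
        ev = simulate_event(np.pi / 4, 10.0, p, fp)
        assert ev.outcome == "crossing"
        assert ev.d[0] > 0 > ev.d[-1]
        np.testing.assert_allclose(ev.speed, p.V0, rtol=1e-6)

    def test_vanishing_gradient_at_huge_lag(self, fp, dyn):
        ev = simulate_event(np.pi / 4, 1e5, dyn, fp)
        assert ev.outcome == "crossing"
        assert ev.max_turn_rate < 1e-3

    def test_reflection_with_speed_minimum_before_turning_point(self, fp, dyn):
        # chemotactic force decelerates the approach and re-accelerates the exit
        ev = simulate_event(np.pi / 4, 10.0, dyn, fp)
        assert ev.outcome == "reflection"
        i_turn = int(np.argmin(np.abs(ev.d)))
        i_vmin = int(np.argmin(ev.speed))
        assert ev.t[i_vmin] < ev.t[i_turn]
        dip = dyn.V0 - ev.speed.min()
        assert dip > 0.01 * dyn.V0  # measurable deceleration on approach
        assert ev.speed[-1] > dyn.V0 - 0.5 * dip  # recovery after the turn

    def test_strong_force_without_torque_traps(self, fp):
        # head-on approach, no aligning torque, overwhelming repulsive force:
        # the droplet stalls at the force balance point
        p = DynamicsParams(alpha_c0=1e7, omega_c0=0.0)
        ev = simulate_event(np.pi / 2, 5.0, p, fp)
        assert ev.outcome == "trapped"

    def test_mirror_symmetry(self, fp, dyn):
        a = simulate_event(np.pi / 3, 15.0, dyn, fp, side=1)
        b = simulate_event(np.pi / 3, 15.0, dyn, fp, side=-1)
        np.testing.assert_array_equal(a.d, b.d)
        np.testing.assert_array_equal(a.xy[:, 1], -b.xy[:, 1])

    def test_single_reflection_to_crossing_switch_in_lag(self, fp, dyn):
        lags = np.geomspace(1.0, 600.0, 100)
        codes = np.array([
            0 if simulate_event(np.pi / 4, lag, dyn, fp).outcome == "reflection" else 1
            for lag in lags
        ])
        assert codes[0] == 0 and codes[-1] == 1
        assert np.all(np.diff(codes) >= 0)  # exactly one switch
        assert np.sum(np.diff(codes) == 1) == 1

    def test_max_turn_rate_decreases_with_lag(self, fp, dyn):
        rates = [simulate_event(np.pi / 3, lag, dyn, fp).max_turn_rate
                 for lag in (5.0, 20.0, 80.0)]
        assert rates[0] > rates[1] > rates[2]

    def test_aging_mode_runs(self, fp, dyn):
        ev = simulate_event(np.pi / 4, 30.0, dyn, fp, trail_mode="aging")
        assert ev.outcome in ("reflection", "crossing")

    @pytest.mark.parametrize("kwargs", [
        {"theta_inc": 0.0, "delta_t": 10.0},
        {"theta_inc": 2.0, "delta_t": 10.0},
        {"theta_inc": 0.5, "delta_t": -1.0},
    ])
    def test_invalid_arguments(self, fp, dyn, kwargs):
        with pytest.raises(ValueError):
            simulate_event(p=dyn, fp=fp, **kwargs)


class TestClassifyEvent:
    line = (np.zeros(2), np.array([1.0, 0.0]))

    def test_straight_line_through_is_crossing(self):
        y = np.linspace(300.0, -300.0, 61)
        xy = np.column_stack([np.linspace(0, 600, 61), y])
        assert classify_event(xy, self.line) == "crossing"

    def test_symmetric_turnaround_is_reflection(self):
        t = np.linspace(0, 1, 101)
        y = 15.0 + (300.0 - 15.0) * (2 * t - 1) ** 2  # dips to +15 µm
        xy = np.column_stack([600 * t, y])
        assert classify_event(xy, self.line) == "reflection"

    def test_tiny_overshoot_counts_as_reflection(self):
        t = np.linspace(0, 1, 201)
        y = -1e-9 + (300.0 + 1e-9) * (2 * t - 1) ** 2  # touches y = -1e-9
        xy = np.column_stack([600 * t, y])
        assert classify_event(xy, self.line) == "reflection"

    def test_never_exits_is_unresolved(self):
        xy = np.column_stack([np.linspace(0, 100, 20), np.full(20, 50.0)])
        assert classify_event(xy, self.line) == "unresolved"

    def test_never_enters_raises(self):
        xy = np.column_stack([np.linspace(0, 100, 20), np.full(20, 500.0)])
        with pytest.raises(ValueError):
            classify_event(xy, self.line)


class TestSeparatrix:
    thetas = np.radians([30.0, 45.0, 60.0, 75.0])

    def test_non_increasing_in_incidence_angle(self, fp, dyn):
        sep = separatrix(self.thetas, dyn, fp)
        vals = sep.delta_t_star
        finite = vals[np.isfinite(vals)]
        assert finite.size >= 2
        assert np.all(np.diff(finite) <= 0.5)  # bisection tolerance

    def test_doubling_torque_delays_crossing(self, fp, dyn):
        import dataclasses
        sep1 = separatrix(self.thetas, dyn, fp)
        sep2 = separatrix(self.thetas, dataclasses.replace(dyn, omega_c0=2 * dyn.omega_c0), fp)
        for a, b in zip(sep1.delta_t_star, sep2.delta_t_star):
            if np.isfinite(a) and np.isfinite(b):
                assert b >= a - 0.5
            elif np.isfinite(a):
                assert np.isnan(b)  # pushed beyond the bracket

    def test_absent_without_torque(self, fp):
        p = DynamicsParams(omega_c0=0.0, alpha_c0=0.0)
        sep = separatrix(self.thetas, p, fp)
        assert np.all(np.isnan(sep.delta_t_star))

    def test_rotational_noise_band_value(self, fp, dyn):
        # delta_theta = sqrt(2 D_r d_max / (V0 sin theta)):
        # at 90 deg, D_r = 0.01, d_max = 220, V0 = 25 -> sqrt(0.176) = 0.420
        sep = separatrix(np.array([np.pi / 2]), dyn, fp, bracket=(1.0, 2.0))
        assert sep.delta_theta[0] == pytest.approx(np.sqrt(2 * 0.01 * 220.0 / 25.0), rel=1e-12)
        assert sep.delta_theta[0] == pytest.approx(0.4195, abs=5e-4)

    def test_crossing_fraction_monotone_in_lag_and_angle(self, fp, dyn):
        # interaction-diagram structure: crossing is more likely for larger
        # lag and for larger incidence angle
        thetas = np.radians([30.0, 60.0, 85.0])
        lags = [5.0, 40.0, 320.0]
        grid = np.array([
            [simulate_event(th, lag, dyn, fp).outcome == "crossing" for lag in lags]
            for th in thetas
        ])
        assert np.all(np.diff(grid.astype(int), axis=1) >= 0)  # along lag
        assert np.all(np.diff(grid.astype(int), axis=0) >= 0)  # along angle


class TestDetectInteractions:
    def make_straight_pair(self):
        # leader along x passes the origin at t = 16 s; follower along -y
        # passes it 30 s later
        V = 25.0
        tL = np.arange(0.0, 32.5, 0.5)
        leader = pd.DataFrame({"droplet_id": 0, "t": tL,
                               "x": -400.0 + V * tL, "y": 0.0})
        tF = np.arange(30.0, 62.5, 0.5)
        follower = pd.DataFrame({"droplet_id": 1, "t": tF,
                                 "x": 0.0, "y": 400.0 - V * (tF - 30.0)})
        return pd.concat([leader, follower], ignore_index=True)

    def test_perpendicular_crossing_geometry(self):
        events = detect_interactions(self.make_straight_pair())
        assert len(events) == 1
        ev = events[0]
        assert ev.outcome == "crossing"
        assert ev.theta_inc == pytest.approx(np.pi / 2, abs=1e-6)
        assert ev.delta_t == pytest.approx(30.0, abs=0.1)
        assert (ev.leader_id, ev.follower_id) == (0, 1)

    def test_parallel_paths_beyond_band_no_events(self):
        t = np.arange(0.0, 40.0, 0.5)
        a = pd.DataFrame({"droplet_id": 0, "t": t, "x": 25.0 * t, "y": 0.0})
        b = pd.DataFrame({"droplet_id": 1, "t": t, "x": 25.0 * t, "y": 300.0})
        assert detect_interactions(pd.concat([a, b], ignore_index=True)) == []

    def test_round_trip_recovers_reflecting_event(self, fp, dyn):
        theta, lag = np.pi / 4, 10.0
        table, gt, ev = gen_event_pair(theta, lag, dyn, fp,
                                       position_noise=0.0, seed=0)
        assert ev.outcome == "reflection"
        events = [e for e in detect_interactions(table)
                  if (e.leader_id, e.follower_id) == (0, 1)]
        assert len(events) == 1
        rec = events[0]
        assert rec.outcome == "reflection"
        assert rec.theta_inc == pytest.approx(theta, abs=np.radians(2.0))
        assert rec.delta_t == pytest.approx(lag, abs=1.0)

    def test_round_trip_recovers_crossing_event(self, fp):
        p = DynamicsParams(alpha_c0=0.0, omega_c0=0.0)
        theta, lag = np.radians(60.0), 25.0
        table, gt, ev = gen_event_pair(theta, lag, p, fp, position_noise=0.0, seed=0)
        assert ev.outcome == "crossing"
        events = [e for e in detect_interactions(table)
                  if (e.leader_id, e.follower_id) == (0, 1)]
        assert len(events) == 1
        assert events[0].outcome == "crossing"
        assert events[0].theta_inc == pytest.approx(theta, abs=np.radians(2.0))
        assert events[0].delta_t == pytest.approx(lag, abs=1.0)
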