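"""Collective simulation, ensemble MSD, caging detection, neighborhoods."""

import dataclasses
import warnings

import numpy as np
import pandas as pd
import pytest

from chemotrails import (
    CollectiveConfig,
    DynamicsParams,
    FieldParams,
    MsdCurve,
    detect_caging,
    ensemble_msd,
    neighborhood_history,
    simulate_collective,
)

# small periodic box for fast runs: shorter trail memory keeps the
# box >= 4 kernel widths
SMALL_FIELD = FieldParams(T_mem=100.0)


def small_cfg(**kwargs):
    defaults = dict(box_size=800.0, number_density=8.0, duration=30.0,
                    field=SMALL_FIELD, seed=3)
    defaults.update(kwargs)
    return CollectiveConfig(**defaults)


class TestSimulateCollective:
    def test_single_droplet_path_is_straight(self):
        # a droplet's own trail lies exactly on its path: zero lateral
        # gradient, so the trajectory stays straight despite self-interaction
        cfg = small_cfg(number_density=2.0, duration=20.0)
        assert cfg.n_droplets == 1
        table, trails = simulate_collective(cfg)
        xy = table[["x", "y"]].to_numpy()
        d = xy - xy[0]
        heading = d[-1] / np.linalg.norm(d[-1])
        lateral = d @ np.array([-heading[1], heading[0]])
        # periodic images of the own trail are not exactly collinear with the
        # path, so "straight" here means sub-nanometre lateral drift
        assert np.max(np.abs(lateral)) < 1e-5

    def test_deterministic_given_seed(self):
        cfg = small_cfg(duration=10.0)
        a, _ = simulate_collective(cfg)
        b, _ = simulate_collective(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_trails_deposited_at_cadence(self):
        cfg = small_cfg(duration=10.0)
        _, trails = simulate_collective(cfg)
        assert len(trails) == cfg.n_droplets
        for tr in trails:
            assert np.allclose(np.diff(tr.times), cfg.dt_deposit)

    def test_box_smaller_than_kernel_support_rejected(self):
        with pytest.raises(ValueError):
            CollectiveConfig(box_size=500.0, field=FieldParams())

    def test_field_overflow_aborts_with_diagnostic(self):
        cfg = small_cfg(number_density=50.0, duration=10.0,
                        dynamics=DynamicsParams(alpha_c0=1e12))
        with pytest.raises(RuntimeError, match="overflow"):
            simulate_collective(cfg)

    def test_3d_mode_runs_and_keeps_unit_orientation(self):
        cfg = small_cfg(dimension=3, number_density=30.0, duration=5.0,
                        record_every=25)
        table, _ = simulate_collective(cfg)
        assert {"z", "nz"} <= set(table.columns)
        norms = np.linalg.norm(table[["nx", "ny", "nz"]].to_numpy(), axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-9)


class TestEnsembleMsd:
    def test_stationary_ensemble_is_zero(self):
        t = np.arange(0.0, 10.0, 0.5)
        table = pd.concat([
            pd.DataFrame({"droplet_id": i, "t": t, "x": 3.0 * i, "y": -1.0 * i})
            for i in range(4)
        ], ignore_index=True)
        curve = ensemble_msd(table)
        assert np.all(curve.msd == 0.0)

    def test_ballistic_closed_form(self):
        # noise-free swimmers at V0 = 25 µm/s: MSD(t) = 625 t² exactly
        t = np.arange(0.0, 20.5, 0.5)
        rows = []
        for i, ang in enumerate(np.linspace(0, np.pi, 5)):
            rows.append(pd.DataFrame({
                "droplet_id": i, "t": t,
                "x": 25.0 * t * np.cos(ang), "y": 25.0 * t * np.sin(ang),
            }))
        curve = ensemble_msd(pd.concat(rows, ignore_index=True))
        np.testing.assert_allclose(curve.msd, 625.0 * curve.lags**2, rtol=1e-12)

    def test_random_walk_matches_diffusion_oracle(self):
        # 2-D random walk with per-axis step variance 2 D dt: MSD = 4 D t
        rng = np.random.default_rng(0)
        D, dt, n_steps, n_walkers = 50.0, 1.0, 200, 300
        steps = rng.normal(0, np.sqrt(2 * D * dt), size=(n_walkers, n_steps, 2))
        paths = np.cumsum(steps, axis=1)
        t = np.arange(1, n_steps + 1) * dt
        rows = [pd.DataFrame({"droplet_id": i,
                              "t": np.concatenate([[0.0], t]),
                              "x": np.concatenate([[0.0], paths[i, :, 0]]),
                              "y": np.concatenate([[0.0], paths[i, :, 1]])})
                for i in range(n_walkers)]
        curve = ensemble_msd(pd.concat(rows, ignore_index=True))
        sel = curve.lags >= 10
        np.testing.assert_allclose(curve.msd[sel], 4 * D * curve.lags[sel], rtol=0.15)

    def test_single_sample_trajectories_excluded_with_warning(self):
        t = np.arange(0.0, 10.0, 0.5)
        good = pd.DataFrame({"droplet_id": 0, "t": t, "x": 25 * t, "y": 0.0})
        stub = pd.DataFrame({"droplet_id": 1, "t": [0.0], "x": [0.0], "y": [0.0]})
        with pytest.warns(UserWarning, match="excluded"):
            curve = ensemble_msd(pd.concat([good, stub], ignore_index=True))
        np.testing.assert_allclose(curve.msd, 625.0 * curve.lags**2, rtol=1e-12)


class TestDetectCaging:
    @staticmethod
    def make_curve(lags, msd):
        return MsdCurve(lags=np.asarray(lags, float), msd=np.asarray(msd, float))

    def test_pure_ballistic_has_no_caging(self):
        lags = np.geomspace(0.1, 1000, 120)
        onset, escape, plateau = detect_caging(self.make_curve(lags, 625 * lags**2))
        assert onset is None and escape is None and plateau is None

    def test_piecewise_curve_breaks_recovered(self):
        # exponent 2 -> 0 -> 1 with breaks at lags 10 and 100
        lags = np.geomspace(0.1, 1000, 121)
        msd = np.where(lags < 10, lags**2,
                       np.where(lags < 100, 100.0, lags))
        onset, escape, plateau = detect_caging(self.make_curve(lags, msd))
        # grid has 30 points/decade; allow the width of the smoothing window
        step = lags[1] / lags[0]
        assert onset is not None and escape is not None
        assert 10 / step**3 <= onset <= 10 * step**3
        assert 100 / step**3 <= escape <= 100 * step**3
        assert plateau == pytest.approx(100.0, rel=0.05)

    def test_constant_curve_is_a_plateau_from_the_start(self):
        lags = np.geomspace(0.1, 1000, 100)
        curve = self.make_curve(lags, np.full_like(lags, 1e4))
        onset, escape, plateau = detect_caging(curve)
        assert onset is not None and onset <= lags[5]
        assert escape is None
        assert plateau == pytest.approx(1e4)

    def test_short_curve_rejected(self):
        with pytest.raises(ValueError):
            detect_caging(self.make_curve([0, 1, 2], [0, 1, 2]))


class TestNeighborhoodHistory:
    @staticmethod
    def table():
        rows = [
            pd.DataFrame({"droplet_id": 0, "t": [100.0], "x": [0.0], "y": [0.0]}),
            # neighbor inside both windows: 100 µm away, 20 s earlier
            pd.DataFrame({"droplet_id": 1, "t": [80.0], "x": [100.0], "y": [0.0]}),
            # outside the time window: 60 s earlier
            pd.DataFrame({"droplet_id": 2, "t": [40.0], "x": [50.0], "y": [0.0]}),
            # outside the spatial window
            pd.DataFrame({"droplet_id": 3, "t": [90.0], "x": [500.0], "y": [0.0]}),
            # in the future: excluded
            pd.DataFrame({"droplet_id": 4, "t": [110.0], "x": [10.0], "y": [0.0]}),
        ]
        return pd.concat(rows, ignore_index=True)

    def test_window_selection(self):
        out = neighborhood_history(self.table(), focal_id=0,
                                   d_window=220.0, t_window=50.0)
        assert set(out["droplet_id"]) == {1}
        assert out["distance"].iloc[0] == pytest.approx(100.0)

    def test_no_other_droplets(self):
        solo = pd.DataFrame({"droplet_id": 0, "t": [0.0, 1.0],
                             "x": [0.0, 25.0], "y": [0.0, 0.0]})
        out = neighborhood_history(solo, focal_id=0)
        assert len(out) == 0

    def test_unknown_focal_id(self):
        with pytest.raises(KeyError):
            neighborhood_history(self.table(), focal_id=99)


class TestDensityTrend:
    def test_crowding_accelerates_slowdown_and_shrinks_cages(self):
        # more crowded systems cross over to the trail-dominated regime
        # earlier and explore less area; medians over 3 seeds per density.
        # Subdiffusion onset (local exponent < 1) and the MSD level at an
        # 80 s lag are used as robust observables at this ensemble size.
        onsets, levels = [], []
        for dens in (3.7, 7.4):
            on_d, lv_d = [], []
            for seed in (1, 2, 3):
                cfg = CollectiveConfig(number_density=dens, box_size=2000.0,
                                       duration=150.0, seed=seed)
                table, _ = simulate_collective(cfg)
                curve = ensemble_msd(table)
                on, _, _ = detect_caging(curve, threshold=1.0)
                on_d.append(on if on is not None else np.inf)
                lv_d.append(float(np.interp(80.0, curve.lags, curve.msd)))
            onsets.append(np.median(on_d))
            levels.append(np.median(lv_d))
        assert onsets[1] <= onsets[0]
        assert levels[1] <= levels[0]
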