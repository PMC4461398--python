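"""Generator: fate rule, population statistics, trajectory shapes, determinism."""

import numpy as np
import pytest

import c8fate as cf
from c8fate.datatypes import FATE_DIED, FATE_SURVIVED, CellParams, PopulationParams


def _degenerate_params(gm_k, theta=1e-3):
    """Zero cell-to-cell spread, noise-free; one dose key."""
    return PopulationParams(
        theta_pop=theta,
        sigma_theta=0.0,
        gm_k_by_dose={25.0: gm_k},
        sigma_k=0.0,
        gm_tau_minus_t0=240.0,
        sigma_tau=0.0,
        t0_sd=0.0,
        noise_sd=0.0,
    )


class TestSampleCells:
    def test_fate_rule_holds_exactly(self, dataset25):
        for c in dataset25.cells:
            died = 2.0 * c.k_true * (c.tau_true - c.t0_true) >= c.theta_cell
            assert (c.fate == FATE_DIED) == died
            if c.fate == FATE_DIED:
                assert c.death_time == c.tau_true
            else:
                assert c.death_time is None

    def test_degenerate_population_all_die(self):
        # GM Max = 2 theta: every cell peaks at twice its threshold
        p = _degenerate_params(gm_k=1e-3 / 240.0)
        cells = cf.sample_cells(p, cf.Scenario("x", 25.0), 50, seed=0)
        assert all(c.fate == FATE_DIED for c in cells)

    def test_degenerate_population_all_survive(self):
        # GM Max = theta / 2
        p = _degenerate_params(gm_k=1e-3 / 960.0)
        cells = cf.sample_cells(p, cf.Scenario("x", 25.0), 50, seed=0)
        assert all(c.fate == FATE_SURVIVED for c in cells)

    @pytest.mark.parametrize("dose", [10.0, 25.0, 500.0])
    def test_kill_fraction_matches_closed_form(self, params, dose):
        n = 10_000
        cells = cf.sample_cells(params, cf.Scenario("d", dose), n, seed=int(dose))
        sim = np.mean([c.fate == FATE_DIED for c in cells])
        expected = cf.expected_kill_fraction(params, dose)
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(sim - expected) <= 3 * se

    def test_kill_monotone_in_rate_duration_and_threshold(self, params):
        n = 10_000

        def kill(scen, seed):
            cells = cf.sample_cells(params, scen, n, seed=seed)
            return np.mean([c.fate == FATE_DIED for c in cells])

        by_dose = [kill(cf.Scenario("d", d), 1) for d in (1.0, 25.0, 500.0)]
        assert by_dose == sorted(by_dose)
        by_tau = [kill(cf.Scenario("t", 25.0, tau_multiplier=m), 2) for m in (1.0, 1.5, 2.0)]
        assert by_tau == sorted(by_tau)
        by_theta = [kill(cf.Scenario("h", 25.0, theta_multiplier=m), 3) for m in (0.5, 1.0, 2.0)]
        assert by_theta == sorted(by_theta, reverse=True)

    def test_survivor_phases_censored_at_horizon(self, dataset25):
        horizon = dataset25.params.horizon
        for c in dataset25.cells:
            if c.fate == FATE_SURVIVED:
                assert c.tau_true <= horizon

    def test_errors(self, params):
        with pytest.raises(ValueError):
            cf.sample_cells(params, cf.Scenario("x", 25.0), 0, seed=0)
        with pytest.raises(KeyError):
            cf.sample_cells(params, cf.Scenario("x", dose_key=33.0), 5, seed=0)


class TestRenderTrajectory:
    def _survivor(self, k=2e-5, t0=20.0, tau=300.0):
        return CellParams("s", k_true=k, t0_true=t0, tau_true=tau,
                          theta_cell=1.0, fate=FATE_SURVIVED)

    def test_quadratic_rise_value(self):
        # FR(120) = k (120 - 20)^2 = 2e-5 * 100^2 = 0.2, noise-free
        p = _degenerate_params(gm_k=1e-6)
        traj = cf.render_trajectory(self._survivor(), p, seed=0)
        i = np.searchsorted(traj.times, 120.0)
        assert traj.fr[i] == pytest.approx(0.2, abs=1e-12)
        assert np.all(traj.fr[traj.times < 20.0] == 0.0)

    def test_survivor_derivative_decays(self):
        p = _degenerate_params(gm_k=1e-6)
        traj = cf.render_trajectory(self._survivor(), p, seed=0)
        d = np.gradient(traj.fr, p.frame_interval)
        at = lambda t: d[np.searchsorted(traj.times, t)]
        tau, tc = 300.0, p.decay_tc
        assert at(tau + 5 * tc) < 0.01 * at(tau - p.frame_interval)

    def test_suppressed_decay_keeps_peak_rate(self):
        p = _degenerate_params(gm_k=1e-6)
        traj = cf.render_trajectory(self._survivor(), p, seed=0, suppress_decay=True)
        d = np.gradient(traj.fr, p.frame_interval)
        peak = 2 * 2e-5 * 280.0
        late = d[np.searchsorted(traj.times, 800.0)]
        assert late == pytest.approx(peak, rel=1e-6)

    def test_dying_trajectory_truncated_on_grid(self):
        p = _degenerate_params(gm_k=1e-6)
        cell = CellParams("d", 2e-5, 20.0, 250.0, 1e-9, FATE_DIED, death_time=250.0)
        traj = cf.render_trajectory(cell, p, seed=0)
        assert traj.times[-1] == 250.0
        cell2 = CellParams("d2", 2e-5, 20.0, 252.0, 1e-9, FATE_DIED, death_time=252.0)
        traj2 = cf.render_trajectory(cell2, p, seed=0)
        assert traj2.times[-1] == 250.0  # last grid point at or before death

    def test_survivors_span_full_record(self, dataset25):
        record = dataset25.params.record_length
        for t in dataset25.trajectories[:50]:
            if t.fate == FATE_SURVIVED:
                assert t.times[-1] == record


class TestGenerateDataset:
    def test_same_seed_byte_identical_csv(self, params, tmp_path):
        scen = cf.Scenario("TRAIL_25", 25.0)
        for sub in ("a", "b"):
            ds = cf.generate_dataset(params, scen, 25, seed=77)
            cf.write_dataset(ds, tmp_path / sub)
        for name in ("trajectories.csv", "cells.csv"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_different_seed_differs(self, params):
        scen = cf.Scenario("TRAIL_25", 25.0)
        a = cf.generate_dataset(params, scen, 10, seed=1)
        b = cf.generate_dataset(params, scen, 10, seed=2)
        n = min(len(a.trajectories[0].fr), len(b.trajectories[0].fr))
        assert not np.allclose(a.trajectories[0].fr[:n], b.trajectories[0].fr[:n])

    def test_cardinality_and_labels(self, dataset25):
        assert len(dataset25.cells) == 300
        assert len(dataset25.trajectories) == 300
        assert all(c.fate in (FATE_DIED, FATE_SURVIVED) for c in dataset25.cells)

    def test_roundtrip_io(self, params, tmp_path):
        ds = cf.generate_dataset(params, cf.Scenario("TRAIL_25", 25.0), 8, seed=5)
        paths = cf.write_dataset(ds, tmp_path)
        loaded = cf.load_trajectories(paths["trajectories"], paths["cells"])
        assert len(loaded) == 8
        np.testing.assert_allclose(loaded[0].fr, ds.trajectories[0].fr)
        assert loaded[0].fate == ds.trajectories[0].fate
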