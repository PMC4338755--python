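from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

import connectosim as cs
from connectosim.dynamics import meanfield_window_means
from conftest import make_random_connectome


PARAMS = cs.MeanFieldParams()


def single_node_connectome():
    return cs.Connectome(np.zeros((1, 1)), np.zeros((1, 3)), ["rS01"])


def uncoupled_fixed_point(params):
    """Smallest root of the gating balance, by scan + Brent bracketing.

    Independent of the integrator: solves -S/tau + (1-S)*gamma*H(w J S + I0)
    = 0 on a fine grid from S=0 upward.
    """

    def g(s):
        h = cs.transfer_rate(params.w * params.j_n * s + params.i_0, params)
        return -s / params.tau_s + (1.0 - s) * params.gamma * h

    grid = np.linspace(0.0, 1.0, 2001)
    vals = np.array([g(s) for s in grid])
    sign_change = np.nonzero((vals[:-1] > 0) & (vals[1:] <= 0))[0]
    assert sign_change.size, "no root bracketed"
    lo, hi = grid[sign_change[0]], grid[sign_change[0] + 1]
    return brentq(g, lo, hi, xtol=1e-12)


class TestTransferRate:
    def test_removable_singularity_equals_one_over_d(self):
        x_sing = PARAMS.b / PARAMS.a  # 0.4 nA
        assert cs.transfer_rate(x_sing, PARAMS) == pytest.approx(
            1.0 / PARAMS.d, rel=1e-12
        )

    def test_reference_values(self):
        # exp term at x=1 is ~1e-11, so H is essentially a*x - b there
        assert cs.transfer_rate(1.0, PARAMS) == pytest.approx(162.0, abs=1e-6)
        assert cs.transfer_rate(0.0, PARAMS) == pytest.approx(6.4600809e-06, rel=1e-6)

    def test_elementwise_and_continuous_near_singularity(self):
        x = np.linspace(0.4 - 1e-6, 0.4 + 1e-6, 101)
        h = cs.transfer_rate(x, PARAMS)
        assert h.shape == x.shape
        assert np.all(np.diff(h) > 0)  # strictly increasing through the joint
        assert np.all(np.abs(h - 1.0 / PARAMS.d) < 1e-3)

    def test_total_and_nonnegative(self):
        x = np.linspace(-5, 5, 1001)
        h = cs.transfer_rate(x, PARAMS)
        assert np.all(np.isfinite(h))
        assert np.all(h >= 0)


class TestSynapticInput:
    def test_zero_state_gives_baseline_current(self, small_conn):
        p = replace(PARAMS, g=2.3)
        x = cs.synaptic_input(np.zeros(small_conn.n_nodes), small_conn, p)
        np.testing.assert_allclose(x, 0.3)

    def test_single_node_recurrent_only(self):
        conn = single_node_connectome()
        x = cs.synaptic_input(np.ones(1), conn, PARAMS)
        assert x[0] == pytest.approx(0.9 * 0.2609 + 0.3)  # 0.53481 nA

    def test_two_node_coupling(self):
        w = np.array([[0.0, 1.0], [1.0, 0.0]])
        conn = cs.Connectome(w, np.zeros((2, 3)), ["rS01"] * 2)
        p = replace(PARAMS, g=2.3)
        x = cs.synaptic_input(np.array([1.0, 0.0]), conn, p)
        assert x[1] == pytest.approx(2.3 * 0.2609 + 0.3)  # 0.90007 nA

    def test_coupling_sign_flag_flips_network_term(self):
        w = np.array([[0.0, 1.0], [1.0, 0.0]])
        conn = cs.Connectome(w, np.zeros((2, 3)), ["rS01"] * 2)
        p = replace(PARAMS, g=2.3, coupling_sign=-1.0)
        x = cs.synaptic_input(np.array([1.0, 0.0]), conn, p)
        assert x[1] == pytest.approx(0.3 - 2.3 * 0.2609)

    def test_dimension_mismatch_rejected(self, small_conn):
        with pytest.raises(ValueError, match="shape"):
            cs.synaptic_input(np.zeros(3), small_conn, PARAMS)


class TestMeanField:
    def test_default_config_emits_10000_samples(self):
        series = cs.simulate_meanfield(single_node_connectome(), PARAMS)
        assert series.n_samples == 10000
        assert series.times[0] == pytest.approx(1e-3)
        assert series.times[-1] == pytest.approx(10.0)
        np.testing.assert_allclose(np.diff(series.times), 1e-3)

    def test_deterministic_without_noise(self, small_conn):
        p = replace(PARAMS, g=0.5)
        cfg = cs.SimulationConfig(duration=0.2)
        a = cs.simulate_meanfield(small_conn, p, cfg)
        b = cs.simulate_meanfield(small_conn, p, cfg)
        np.testing.assert_array_equal(a.s, b.s)

    def test_seeded_noise_reproducible_and_seed_sensitive(self, small_conn):
        p = replace(PARAMS, g=0.5, sigma=0.05)
        cfg = cs.SimulationConfig(duration=0.2, seed=11)
        a = cs.simulate_meanfield(small_conn, p, cfg)
        b = cs.simulate_meanfield(small_conn, p, cfg)
        np.testing.assert_array_equal(a.s, b.s)
        c = cs.simulate_meanfield(small_conn, p, replace(cfg, seed=12))
        assert not np.array_equal(a.s, c.s)

    def test_uncoupled_terminal_state_matches_balance_oracle(self):
        series = cs.simulate_meanfield(
            single_node_connectome(), PARAMS, cs.SimulationConfig(duration=6.0)
        )
        assert abs(series.s[-1, 0] - uncoupled_fixed_point(PARAMS)) < 1e-6

    def test_euler_error_shrinks_linearly_with_dt(self, small_conn):
        """Noise-free trajectories converge at first order in the step size."""
        p = replace(PARAMS, g=0.8)
        end = {}
        for dt in (4e-4, 2e-4, 1e-4):
            cfg = cs.SimulationConfig(dt=dt, duration=0.4, sample_interval=4e-2)
            end[dt] = cs.simulate_meanfield(small_conn, p, cfg).s[-1]
        e_coarse = np.abs(end[4e-4] - end[1e-4]).max()
        e_fine = np.abs(end[2e-4] - end[1e-4]).max()
        # halving dt roughly halves the deviation (ratio ~ 3 for O(dt) with
        # Richardson-style geometry; allow a generous band around it)
        assert 1.5 < e_coarse / e_fine < 6.0

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 1000), sigma=st.floats(0.0, 0.3))
    def test_gating_stays_in_unit_interval(self, seed, sigma):
        conn = make_random_connectome(n=8, seed=3)
        p = replace(PARAMS, g=1.5, sigma=sigma)
        cfg = cs.SimulationConfig(duration=0.05, seed=seed)
        series = cs.simulate_meanfield(conn, p, cfg)
        assert series.s.min() >= 0.0
        assert series.s.max() <= 1.0

    def test_permutation_equivariance(self):
        conn = make_random_connectome(n=9, seed=7)
        perm = np.array([4, 0, 8, 2, 6, 1, 5, 3, 7])
        permuted = cs.Connectome(
            conn.weights[np.ix_(perm, perm)],
            conn.coordinates[perm],
            [conn.region_labels[i] for i in perm],
        )
        p = replace(PARAMS, g=0.9)
        cfg = cs.SimulationConfig(duration=0.1)
        a = cs.simulate_meanfield(conn, p, cfg)
        b = cs.simulate_meanfield(permuted, p, cfg)
        np.testing.assert_allclose(b.s, a.s[:, perm], rtol=0, atol=1e-14)

    def test_overflow_reported_as_integration_error(self):
        conn = single_node_connectome()
        cfg = cs.SimulationConfig(duration=0.1, initial_s=1e160, clamp_s=False)
        with pytest.raises(cs.IntegrationError, match="step"):
            cs.simulate_meanfield(conn, PARAMS, cfg)

    def test_sampling_grid_must_be_commensurate(self):
        with pytest.raises(ValueError, match="multiple"):
            cs.SimulationConfig(dt=3e-4, sample_interval=1e-3).validate()

    def test_batch_means_match_single_runs(self, small_conn):
        p = replace(PARAMS, g=0.5)
        cfg = cs.SimulationConfig(duration=0.3)
        runs = [(0.05, 0), (0.0, 4)]
        means, _ = meanfield_window_means(
            small_conn, p, cfg, runs, window=(0.1, 0.3)
        )
        for row, (sigma, seed) in zip(means, runs):
            series = cs.simulate_meanfield(
                small_conn, replace(p, sigma=sigma), replace(cfg, seed=seed)
            )
            sel = (series.times >= 0.1 - 1e-12) & (series.times <= 0.3 + 1e-12)
            np.testing.assert_array_equal(row, series.rate[sel].mean(axis=0))


class TestLinearThreshold:
    def test_unreachable_threshold_silences_network(self, small_conn):
        p = cs.ThresholdParams(theta=1e9, noise_sd=0.0)
        series = cs.simulate_linear_threshold(
            small_conn, p, cs.SimulationConfig(duration=0.05, initial_s=0.5)
        )
        assert np.all(series.rate == 0.0)

    def test_constant_input_above_threshold_closed_form(self):
        conn = single_node_connectome()
        stim = cs.make_stimulation([1], 2.5, 0.0, 0.05)
        p = cs.ThresholdParams(theta=1.0, gain=1.0, noise_sd=0.0)
        series = cs.simulate_linear_threshold(
            conn, p, cs.SimulationConfig(duration=0.05, initial_s=0.0),
            protocol=[stim],
        )
        np.testing.assert_allclose(series.rate, 1.5)

    def test_two_node_chain_matches_manual_unroll(self):
        w = np.array([[0.0, 0.5], [0.5, 0.0]])
        conn = cs.Connectome(w, np.zeros((2, 3)), ["rS01"] * 2)
        p = cs.ThresholdParams(theta=0.1, gain=2.0, noise_sd=0.0)
        cfg = cs.SimulationConfig(
            dt=1e-3, sample_interval=1e-3, duration=5e-3, initial_s=1.0
        )
        series = cs.simulate_linear_threshold(conn, p, cfg)
        a = np.array([1.0, 1.0])
        expected = []
        for _ in range(5):
            a = p.gain * np.maximum(0.0, w @ a - p.theta)
            expected.append(a.copy())
        np.testing.assert_allclose(series.rate, np.array(expected))


class TestSigmoid:
    def test_full_decay_has_no_memory(self):
        # uncoupled nodes, full decay: activity is the per-step drive alone,
        # so after one step the initial state is forgotten entirely
        conn = cs.Connectome(np.zeros((3, 3)), np.zeros((3, 3)), ["rS01"] * 3)
        p = cs.SigmoidParams(theta=0.5, gain=1.0, decay=1.0, r_max=2.0)
        cfg = cs.SimulationConfig(dt=1e-3, sample_interval=1e-3, duration=5e-3)
        a = cs.simulate_sigmoid(conn, p, replace(cfg, initial_s=0.0))
        b = cs.simulate_sigmoid(conn, p, replace(cfg, initial_s=0.9))
        np.testing.assert_allclose(a.rate[1:], b.rate[1:], atol=1e-12)

    def test_geometric_decay_without_drive(self):
        conn = single_node_connectome()
        lam = 0.25
        p = cs.SigmoidParams(theta=0.0, gain=1.0, decay=lam, r_max=0.0)
        cfg = cs.SimulationConfig(
            dt=1e-3, sample_interval=1e-3, duration=6e-3, initial_s=1.0
        )
        series = cs.simulate_sigmoid(conn, p, cfg)
        expected = (1 - lam) ** np.arange(1, 7)
        np.testing.assert_allclose(series.rate[:, 0], expected, rtol=1e-12)

    def test_logistic_at_threshold_gives_half_maximum_drive(self):
        conn = single_node_connectome()
        p = cs.SigmoidParams(theta=0.7, gain=3.0, decay=1.0, r_max=2.0)
        stim = cs.make_stimulation([1], 0.7, 0.0, 2e-3)
        cfg = cs.SimulationConfig(
            dt=1e-3, sample_interval=1e-3, duration=2e-3, initial_s=0.0
        )
        series = cs.simulate_sigmoid(conn, p, cfg, protocol=[stim])
        assert series.rate[-1, 0] == pytest.approx(p.r_max / 2)


class TestCalibration:
    def test_uncoupled_network_has_no_bifurcation(self):
        conn = cs.Connectome(np.zeros((3, 3)), np.zeros((3, 3)), ["rS01"] * 3)
        with pytest.raises(cs.CalibrationError, match="no bifurcation"):
            cs.calibrate_g(conn, PARAMS, scan_range=(0.1, 5.0), duration=1.0)

    def test_bisection_certificate(self):
        """The low state is stable just below the returned G and unstable just above."""
        n = 10
        w = np.ones((n, n)) - np.eye(n)
        conn = cs.Connectome(w, np.zeros((n, 3)), ["rS01"] * n)
        tol = 0.01
        g = cs.calibrate_g(conn, PARAMS, scan_range=(0.01, 2.0), tol=tol, duration=3.0)

        def low_state_rate(gv):
            p = replace(PARAMS, g=gv)
            cfg = cs.SimulationConfig(duration=3.0, sample_interval=1e-2)
            series = cs.simulate_meanfield(conn, p, cfg)
            return series.rate[-60:].mean()

        assert low_state_rate(g - tol) <= 20.0
        assert low_state_rate(g + tol) > 20.0
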