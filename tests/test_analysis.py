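import math
from dataclasses import replace

import numpy as np
import pytest

import connectosim as cs
from conftest import make_random_connectome


def series_from_rates(rate, dt=1e-3, lesion_mask=None):
    rate = np.asarray(rate, dtype=float)
    times = np.arange(1, rate.shape[0] + 1) * dt
    return cs.RateTimeSeries(times=times, rate=rate, lesion_mask=lesion_mask)


class TestMeanFiring:
    def test_constant_series(self):
        series = series_from_rates(np.full((10_000, 4), 40.0))
        summary = cs.mean_firing(series)
        np.testing.assert_allclose(summary.per_node_mean, 40.0)
        assert summary.total == pytest.approx(160.0)
        assert summary.window == (8.0, 10.0)

    def test_linear_ramp_last_two_seconds(self):
        # rate(t) = 10 t over 10 s: samples in [8 s, 10 s] average to 90 Hz
        times = np.arange(1, 10_001) * 1e-3
        rate = (10.0 * times)[:, None]
        series = series_from_rates(rate)
        summary = cs.mean_firing(series)
        sel = times >= 8.0 - 1e-12
        assert summary.per_node_mean[0] == pytest.approx(10 * times[sel].mean())
        assert summary.per_node_mean[0] == pytest.approx(90.0, abs=0.01)

    def test_full_span_window_of_constant_series(self):
        series = series_from_rates(np.full((100, 2), 7.0))
        summary = cs.mean_firing(series, window=(series.times[0], series.times[-1]))
        np.testing.assert_allclose(summary.per_node_mean, 7.0)

    def test_window_outside_span_rejected(self):
        series = series_from_rates(np.zeros((100, 2)))
        with pytest.raises(ValueError, match="window"):
            cs.mean_firing(series, window=(0.0, 5.0))

    def test_masked_nodes_excluded_from_total(self):
        mask = np.array([False, True, False])
        series = series_from_rates(np.full((100, 3), 10.0), lesion_mask=mask)
        summary = cs.mean_firing(series, window=(0.05, 0.1))
        assert summary.total == pytest.approx(20.0)
        assert summary.per_node_mean[1] == pytest.approx(10.0)  # reported anyway

    def test_total_additive_over_node_partitions(self):
        rng = np.random.default_rng(1)
        rate = rng.uniform(0, 100, (500, 6))
        summary = cs.mean_firing(series_from_rates(rate), window=(0.1, 0.5))
        parts = [summary.per_node_mean[:3].sum(), summary.per_node_mean[3:].sum()]
        assert summary.total == pytest.approx(sum(parts))


class TestDeltaFr:
    def test_identical_runs_give_zero(self, small_conn):
        p = replace(cs.MeanFieldParams(), g=0.5)
        cfg = cs.SimulationConfig(duration=0.1)
        a = cs.mean_firing(cs.simulate_meanfield(small_conn, p, cfg))
        b = cs.mean_firing(cs.simulate_meanfield(small_conn, p, cfg))
        np.testing.assert_array_equal(cs.delta_fr(a, b), 0.0)

    def test_total_of_delta_equals_difference_of_totals(self):
        rng = np.random.default_rng(2)
        a = cs.mean_firing(series_from_rates(rng.uniform(0, 50, (100, 5))), window=(0.05, 0.1))
        b = cs.mean_firing(series_from_rates(rng.uniform(0, 50, (100, 5))), window=(0.05, 0.1))
        assert cs.delta_fr(a, b).sum() == pytest.approx(a.total - b.total)

    def test_shape_mismatch_rejected(self):
        a = cs.mean_firing(series_from_rates(np.zeros((10, 3))), window=(0.005, 0.01))
        b = cs.mean_firing(series_from_rates(np.zeros((10, 4))), window=(0.005, 0.01))
        with pytest.raises(ValueError, match="nodes"):
            cs.delta_fr(a, b)

    def test_largest_deltas_concentrate_near_lesion(self, calibrated):
        """After a focal lesion, the strongest rate drops sit on the nodes
        most strongly coupled to the lesioned set."""
        conn, params = calibrated
        les = cs.focal_lesion(conn.atlas, ["rCUN", "rLOCC", "rPCUN"])
        p = replace(params, sigma=0.01)
        cfg = cs.SimulationConfig(duration=10.0, seed=0)
        healthy = cs.mean_firing(cs.simulate_meanfield(conn, p, cfg))
        lesioned = cs.mean_firing(cs.simulate_meanfield(conn, p, cfg, protocol=[les]))
        delta = cs.delta_fr(healthy, lesioned)
        idx = conn.index_of(np.asarray(les.node_set))
        outside = np.ones(conn.n_nodes, bool)
        outside[idx] = False
        coupling = conn.weights[:, idx].sum(axis=1)
        top = np.argsort(np.abs(delta * outside))[-50:]
        assert coupling[top].mean() > 2.0 * coupling[outside].mean()


class TestReturnToBaseline:
    def baseline(self, mean=10.0, sd=1.0):
        return cs.FiringSummary(
            per_node_mean=np.array([mean]), window=(0.0, 1.0), total=mean,
            node_avg_mean=mean, node_avg_sd=sd,
        )

    def test_series_already_at_baseline_returns_zero(self):
        series = series_from_rates(np.full((1000, 1), 10.0))
        assert cs.return_to_baseline(series, 0.5, self.baseline()) == 0.0

    def test_unperturbed_series_against_itself(self):
        rng = np.random.default_rng(3)
        rate = 10.0 + 0.1 * rng.standard_normal((1000, 1))
        series = series_from_rates(rate)
        summary = cs.mean_firing(series, window=(0.5, 1.0))
        assert cs.return_to_baseline(series, 0.5, summary, k_sd=3.0) == 0.0

    def test_exponential_relaxation_matches_analytic_crossing(self):
        # trace = 10 + A exp(-t/tau): crosses the k*sd band at
        # t = tau * log(A / (k*sd))
        tau, amp, k_sd, sd = 0.05, 8.0, 2.0, 0.5
        times = np.arange(1, 2001) * 1e-3
        rate = (10.0 + amp * np.exp(-times / tau))[:, None]
        series = series_from_rates(rate)
        got = cs.return_to_baseline(series, 0.0, self.baseline(sd=sd), k_sd=k_sd)
        expected_ms = tau * math.log(amp / (k_sd * sd)) * 1000
        assert abs(got - expected_ms) <= 1.0 + 1e-9  # within one sample

    def test_never_returning_series_yields_sentinel(self):
        series = series_from_rates(np.full((100, 1), 50.0))
        out = cs.return_to_baseline(series, 0.05, self.baseline())
        assert math.isnan(out)

    def test_monotone_in_band_width(self):
        rng = np.random.default_rng(4)
        rate = (10 + 5 * np.exp(-np.arange(1, 3001) / 400.0)
                + 0.3 * rng.standard_normal(3000))[:, None]
        series = series_from_rates(rate)
        base = self.baseline(sd=0.3)
        latencies = [
            cs.return_to_baseline(series, 0.1, base, k_sd=k) for k in (1.0, 2.0, 4.0)
        ]
        clean = [t for t in latencies if not math.isnan(t)]
        assert clean == sorted(clean, reverse=True)

    def test_offset_outside_span_rejected(self):
        series = series_from_rates(np.zeros((10, 1)))
        with pytest.raises(ValueError, match="t_offset"):
            cs.return_to_baseline(series, 5.0, self.baseline())


class TestNoiseScan:
    def test_duplicated_sigma_gives_identical_totals(self, small_conn):
        p = replace(cs.MeanFieldParams(), g=0.5)
        cfg = cs.SimulationConfig(duration=0.2)
        table = cs.noise_scan(small_conn, p, [0.0, 0.0], cfg)
        totals = table["total_rate_hz"].to_numpy()
        assert totals[0] == totals[1]

    def test_end_to_end_reproducible(self, small_conn):
        p = replace(cs.MeanFieldParams(), g=0.5)
        cfg = cs.SimulationConfig(duration=0.2)
        a = cs.noise_scan(small_conn, p, [0.02, 0.05], cfg, seeds=[3, 4])
        b = cs.noise_scan(small_conn, p, [0.02, 0.05], cfg, seeds=[3, 4])
        assert a.equals(b)
        assert list(a.columns) == ["sigma", "seed", "total_rate_hz"]
        assert len(a) == 4

    def test_empty_sigma_list_rejected(self, small_conn):
        with pytest.raises(ValueError, match="non-empty"):
            cs.noise_scan(small_conn, cs.MeanFieldParams(), [], cs.SimulationConfig())
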