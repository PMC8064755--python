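"""Filament trace statistics against exact hand-computed and closed-form
oracles, plus the reshuffle and binomial-partition controls."""

import numpy as np
import pytest

from filaclock import stats
from filaclock.synth import synth_snapshot


def _traces(values, dt=0.5, **kw):
    values = np.asarray(values, dtype=float)
    t = np.arange(values.shape[1]) * dt
    return stats.FilamentTraces(values=values, time_hr=t, **kw)


class TestSyncIndex:
    def test_identical_traces_give_one(self):
        x = 2.0 + np.sin(np.linspace(0, 12, 100))
        tr = _traces(np.tile(x, (6, 1)))
        assert stats.sync_index(tr).R == pytest.approx(1.0)

    def test_independent_noise_gives_one_over_n(self):
        rng = np.random.default_rng(0)
        f = 10.0 + rng.standard_normal((10, 5000))
        R = stats.sync_index(f).R
        assert R == pytest.approx(0.1, abs=0.02)

    def test_common_signal_plus_noise_matches_closed_form(self):
        """R for a shared sinusoid with independent additive noise equals
        (S + N/n) / (S + N) with signal power S and noise power N."""
        rng = np.random.default_rng(1)
        n, T = 8, 20000
        t = np.arange(T) * 0.5
        sig = np.sin(2 * np.pi * t / 24.0)
        S = np.var(sig)
        N = 0.5 ** 2
        f = 5.0 + sig + 0.5 * rng.standard_normal((n, T))
        expected = (S + N / n) / (S + N)
        assert stats.sync_index(f).R == pytest.approx(expected, rel=0.03)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            stats.sync_index(np.ones((3, 50)))
        with pytest.raises(ValueError):
            stats.sync_index(np.random.default_rng(0).random((1, 50)))

    def test_sqrt_option_and_reshuffle_invariance(self):
        rng = np.random.default_rng(2)
        tr = _traces(1 + rng.random((12, 200)))
        res = stats.sync_index(tr)
        assert stats.sync_index(tr, sqrt=True).R == pytest.approx(np.sqrt(res.R))
        shuf = stats.reshuffle_control(tr, seed=5)
        assert stats.sync_index(shuf).R == pytest.approx(res.R)

    def test_adding_noise_reduces_synchrony(self):
        rng = np.random.default_rng(3)
        x = 5 + np.sin(np.linspace(0, 30, 400))
        clean = np.tile(x, (6, 1))
        noisy = clean + 0.3 * rng.standard_normal(clean.shape)
        assert stats.sync_index(noisy).R < stats.sync_index(clean).R


class TestSpatialAutocorr:
    def test_hand_computed_example(self):
        res = stats.spatial_autocorr(np.array([1.0, 3.0, 2.0]), max_lag=2)
        assert res.g[0] == 1.0
        assert res.g[1] == pytest.approx(-0.5)
        # c_0 = 2/3, c_1 = -1/3 with the divisor-N estimator

    def test_g0_is_exactly_one(self):
        rng = np.random.default_rng(4)
        res = stats.spatial_autocorr(rng.random(50), max_lag=10)
        assert res.g[0] == 1.0
        assert np.all(np.abs(res.g) <= 1.0 + 1e-12)

    def test_recovers_synthetic_correlation_length(self):
        """AR(1) filaments with decay length 3 cells: the averaged estimator
        recovers it within 20% (long filaments; the divisor-N estimator is
        biased low on 50-cell filaments)."""
        gs = [stats.spatial_autocorr(synth_snapshot(200, 3.0, seed=s), max_lag=10)
              for s in range(50)]
        g = stats.average_autocorr(gs)
        ell = stats.fit_correlation_length(g, max_fit_lag=5)
        assert ell == pytest.approx(3.0, rel=0.2)

    def test_errors(self):
        with pytest.raises(ValueError):
            stats.spatial_autocorr(np.ones(40), max_lag=10)
        with pytest.raises(ValueError):
            stats.spatial_autocorr(np.arange(5.0), max_lag=10)


class TestCV2:
    def test_hand_computed_and_invariances(self):
        f = np.array([[1.0], [3.0]])
        assert stats.cv2_series(f)[0] == pytest.approx(0.25)
        assert np.all(stats.cv2_series(np.tile([[5.0]], (4, 3))) == 0.0)
        rng = np.random.default_rng(5)
        x = 1 + rng.random((6, 40))
        np.testing.assert_allclose(stats.cv2_series(3.7 * x),
                                   stats.cv2_series(x), rtol=1e-12)

    def test_zero_mean_flagged_not_fatal(self):
        f = np.zeros((3, 4))
        f[:, 1] = [1, 2, 3]
        out = stats.cv2_series(f)
        assert np.isnan(out[0]) and np.isfinite(out[1])


class TestBinomialPartitionNull:
    def test_partition_conserves_mean(self):
        snap = np.full(20, 400.0)
        means = []
        for s in range(300):
            vals, _ = stats.binomial_partition_null(snap, generations=1, seed=s)
            means.append(vals.mean())
        assert np.mean(means) == pytest.approx(400.0, rel=0.01)

    def test_null_autocorrelation_vanishes_beyond_first_neighbor(self):
        """Inheritance alone decorrelates by the second neighbour."""
        snap = synth_snapshot(60, 5.0, seed=7, mean=500, sd=100)
        gs = []
        for s in range(40):
            _, g = stats.binomial_partition_null(snap, generations=3, seed=s)
            gs.append(g)
        g = stats.average_autocorr(gs)
        n_cells = 60 * 8
        assert np.all(np.abs(g.g[2:8]) < 2.0 / np.sqrt(n_cells) + 0.02)

    def test_zero_generations_returns_reshuffled_input(self):
        snap = np.arange(40.0)
        vals, _ = stats.binomial_partition_null(snap, generations=0, seed=3)
        assert sorted(vals) == sorted(snap)
        assert not np.array_equal(vals, snap)

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            stats.binomial_partition_null(np.array([-1.0, 2.0]), seed=0)


class TestDivisionPhases:
    def test_linear_phase_map(self):
        h = stats.division_phase_histogram([22.0], [10.0, 34.0], n_bins=8)
        # phase pi falls in bin 4 of 8
        assert h.counts[4] == 1 and h.counts.sum() == 1

    def test_divisions_at_minima_fill_edge_bins(self):
        minima = [0.0, 24.0, 48.0, 72.0]
        divs = [0.01, 23.9, 24.05, 47.9, 48.1]
        h = stats.division_phase_histogram(divs, minima, n_bins=10)
        assert h.counts[0] + h.counts[-1] == len(divs)

    def test_uniform_divisions_give_uniform_histogram(self):
        rng = np.random.default_rng(8)
        minima = np.arange(0.0, 240.1, 24.0)
        divs = rng.uniform(0.0, 240.0, 3000)
        h = stats.division_phase_histogram(divs, minima, n_bins=10)
        expected = h.n_divisions / 10
        assert np.all(np.abs(h.counts - expected) < 5 * np.sqrt(expected))

    def test_out_of_cycle_divisions_counted(self):
        h = stats.division_phase_histogram([5.0, 50.0], [10.0, 34.0], n_bins=4)
        assert h.n_excluded == 2 and h.n_divisions == 0


class TestCoherenceEstimate:
    def test_distance_zero_is_one(self):
        rng = np.random.default_rng(9)
        tr = _traces(1 + rng.random((40, 300)))
        coh = stats.coherence_estimate(tr, segment_cells=40, discard_initial_hr=0)
        assert coh.values[0] == 1.0 + 0j

    def test_common_sinusoid_with_noise_matches_power_ratio(self):
        """|coherence| is flat in distance and equals the signal/(signal+noise)
        power ratio at the oscillation frequency."""
        rng = np.random.default_rng(10)
        n, T, dt = 70, 480, 0.5
        t = np.arange(T) * dt
        f0 = 1 / 24.0
        sig = np.sin(2 * np.pi * f0 * t)
        noise = rng.standard_normal((n, T))
        tr = _traces(10 + sig + 1.0 * noise, dt=dt)
        coh = stats.coherence_estimate(tr, frequency_per_hr=f0,
                                       segment_cells=35, d_max=8,
                                       discard_initial_hr=0)
        # expected ratio: sinusoid periodogram power vs noise power in the bin
        mag = np.abs(coh.values[1:])
        assert mag.std() < 0.15
        # signal dominates its own bin: ratio close to Psig/(Psig+Pnoise)
        x = sig
        Ps = np.abs(np.fft.rfft(x - x.mean()))[np.argmin(np.abs(
            np.fft.rfftfreq(T, dt) - f0))] ** 2
        Pn = np.mean(np.abs(np.fft.rfft(noise - noise.mean(axis=1, keepdims=True),
                                        axis=1))[:, np.argmin(np.abs(
            np.fft.rfftfreq(T, dt) - f0))] ** 2)
        expected = Ps / (Ps + Pn)
        assert np.mean(mag) == pytest.approx(expected, abs=0.1)

    def test_reshuffling_flattens_spatially_correlated_coherence(self, fitted_params):
        from filaclock import filament as fl
        kern = fl.CouplingKernel(range_cells=2.0, strength=0.5)
        arr = fl.gillespie_array(fitted_params, 35, kern, 2000, 600.0, seed=77)
        tr = stats.FilamentTraces(values=arr.species_concentration("T"),
                                  time_hr=arr.time_hr)
        coh = stats.coherence_estimate(tr, segment_cells=35, d_max=8,
                                       discard_initial_hr=50)
        shuf = stats.reshuffle_control(tr, seed=2)
        coh_s = stats.coherence_estimate(shuf, segment_cells=35, d_max=8,
                                         discard_initial_hr=50)
        mag, mag_s = np.abs(coh.values[1:]), np.abs(coh_s.values[1:])
        # structured curve decays; reshuffled one is flat by comparison
        assert mag[0] - mag[-1] > 2 * abs(mag_s[0] - mag_s[-1])


class TestReshuffleControl:
    def test_preserves_traces_and_kills_spatial_structure(self):
        snap_like = np.array([synth_snapshot(120, 4.0, seed=s) for s in range(3)])
        tr = _traces(snap_like.T)  # 120 cells x 3 timepoints
        shuf = stats.reshuffle_control(tr, seed=11)
        assert sorted(map(tuple, shuf.values)) == sorted(map(tuple, tr.values))
        g = stats.spatial_autocorr(tr.values[:, 0], max_lag=8)
        g_s = stats.spatial_autocorr(shuf.values[:, 0], max_lag=8)
        assert abs(g_s.g[1]) < abs(g.g[1])
        assert np.all(np.abs(g_s.g[1:4]) < 0.25)


class TestMinimaDetection:
    def test_finds_minima_of_noisy_oscillation(self):
        rng = np.random.default_rng(12)
        t = np.arange(0, 120, 0.5)
        mu = 10 - 3 * np.cos(2 * np.pi * t / 24.0) + 0.2 * rng.standard_normal(t.size)
        minima = stats.detect_minima(mu, t)
        expected = np.arange(0.0, 120.0, 24.0)
        found = [m for m in minima if 5 < m < 115]
        for m in found:
            assert np.min(np.abs(expected - m)) < 3.0
        assert len(found) >= 3
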