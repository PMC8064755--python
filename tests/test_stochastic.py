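"""Exact SSA of the single-clock master equation and LNA spectra."""

import numpy as np
import pytest
from scipy import stats as sps

from filaclock import kai_core as kc
from filaclock import stochastic as st
from filaclock.params import SOURCE_SPECIES, STOICHIOMETRY


class TestPropensities:
    def test_zero_when_source_empty(self, fitted_params):
        s = st.ClockState(n_T=0, n_D=5, n_S=3, N_tot=100)
        a = st.propensities(s, fitted_params)
        # T -> U and T -> D have no molecules to convert
        assert a[1] == 0.0 and a[2] == 0.0
        assert np.all(a >= 0.0)

    def test_extensive_in_system_size(self, fitted_params):
        s1 = st.ClockState(n_T=20, n_D=30, n_S=10, N_tot=100)
        s2 = st.ClockState(n_T=40, n_D=60, n_S=20, N_tot=200)
        np.testing.assert_allclose(st.propensities(s2, fitted_params),
                                   2.0 * st.propensities(s1, fitted_params),
                                   rtol=1e-12)

    def test_matches_deterministic_fluxes_at_fixed_point(self, fitted_params):
        """Net propensity flux at the discretized fixed point reproduces
        ode_rhs up to 1/N discreteness."""
        N = 100000
        fp = kc.find_fixed_point(fitted_params)
        counts = np.round(fp.as_array() * N / fitted_params.C_tot).astype(int)
        s = st.ClockState(*counts, N_tot=N)
        a = st.propensities(s, fitted_params)
        net = (a @ STOICHIOMETRY.astype(float)) * fitted_params.C_tot / N
        np.testing.assert_allclose(net, kc.ode_rhs(fp.as_array(), fitted_params),
                                   atol=5e-4)


class TestGillespie:
    def test_bit_reproducible_with_fixed_seed(self, fitted_params):
        a = st.gillespie_single(fitted_params, 500, 50.0, seed=42)
        b = st.gillespie_single(fitted_params, 500, 50.0, seed=42)
        np.testing.assert_array_equal(a.counts, b.counts)
        c = st.gillespie_single(fitted_params, 500, 50.0, seed=43)
        assert not np.array_equal(a.counts, c.counts)

    def test_conservation_and_positivity(self, fitted_params):
        traj = st.gillespie_single(fitted_params, 200, 100.0, seed=7)
        assert np.all(traj.counts >= 0)
        assert np.all(traj.counts.sum(axis=1) <= 200)

    def test_single_molecule_limit(self, fitted_params):
        traj = st.gillespie_single(fitted_params, 1, 200.0, seed=11)
        assert set(np.unique(traj.counts)) <= {0, 1}
        assert np.all(traj.counts.sum(axis=1) <= 1)

    def test_waiting_times_are_exponential(self, fitted_params):
        """First inter-event time across seeds is Exp(total propensity of the
        initial state) — exactness of the direct method."""
        N = 1000
        counts0 = st._initial_counts(fitted_params, N, None)
        s0 = st.ClockState(*counts0, N_tot=N)
        a0 = st.propensities(s0, fitted_params).sum()
        first = np.array([
            st.gillespie_waiting_times(fitted_params, N, 1, seed=1000 + i)[0][0]
            for i in range(10000)])
        ks = sps.kstest(first, "expon", args=(0, 1.0 / a0))
        assert ks.pvalue > 0.01

    def test_long_run_mean_near_fixed_point(self, circadian_focus_params):
        p = circadian_focus_params
        traj = st.gillespie_single(p, 5000, 2000.0, seed=5)
        x = traj.species_concentration("T")[400:]
        fp = kc.find_fixed_point(p)
        C = st.stationary_covariance(p, 5000)
        n_eff = x.size / 50.0   # generous correlation-time discount
        se = np.sqrt(C[0, 0] / n_eff)
        assert abs(x.mean() - fp.phi_T) < 3 * se


class TestLNA:
    def test_diffusion_matrix_construction(self, fitted_params):
        """B is symmetric PSD and equals the independent per-reaction sum."""
        J, B = st.lna_matrices(fitted_params)
        np.testing.assert_allclose(B, B.T, atol=1e-14)
        assert np.linalg.eigvalsh(B).min() > -1e-12
        fp = kc.find_fixed_point(fitted_params)
        A = kc.active_kaiA(fp.phi_S, fitted_params, check=False)
        k = kc.transition_rates(A, fitted_params.kinetics)
        pools = np.array([fp.phi_U, fp.phi_T, fp.phi_D, fp.phi_S])
        B2 = np.zeros((3, 3))
        for r in range(8):
            nu = STOICHIOMETRY[r].astype(float)
            B2 += np.outer(nu, nu) * k[r] * pools[SOURCE_SPECIES[r]]
        np.testing.assert_allclose(B, B2, rtol=1e-12)

    def test_lyapunov_covariance_matches_ssa(self):
        """Validated at a well-damped focus where the linear approximation is
        quantitatively accurate (near the Hopf point it overestimates the
        variance by design of the expansion)."""
        from filaclock.params import default_params
        p = default_params(gamma=2.5, kaiA_total=1.3)
        C = st.stationary_covariance(p, 5000)
        vs = [st.gillespie_single(p, 5000, 4000.0, seed=s)
              .species_concentration("T")[400:].var() for s in (9, 19, 29, 39)]
        assert np.mean(vs) == pytest.approx(C[0, 0], rel=0.10)

    def test_wiener_khinchin(self, fitted_params):
        """Integral of the analytic spectrum equals the Lyapunov variance."""
        f = np.linspace(1e-4, 3.0, 20000)
        sp = st.analytic_power_spectrum(fitted_params, 5000, "T", f)
        var_spec = np.trapezoid(sp.psd, sp.freq_per_hr)
        C = st.stationary_covariance(fitted_params, 5000)
        assert var_spec == pytest.approx(C[0, 0], rel=0.01)

    def test_peak_at_quasi_cycle_frequency(self, circadian_focus_params):
        sp = st.analytic_power_spectrum(circadian_focus_params, 5000, "T")
        J, _ = st.lna_matrices(circadian_focus_params)
        ev = np.linalg.eigvals(J)
        f_lin = np.abs(ev.imag).max() / (2 * np.pi)
        assert sp.peak_freq_per_hr == pytest.approx(f_lin, rel=0.10)

    def test_spectrum_scales_inversely_with_system_size(self, fitted_params):
        f = np.linspace(0.01, 0.1, 20)
        s1 = st.analytic_power_spectrum(fitted_params, 5000, "T", f)
        s2 = st.analytic_power_spectrum(fitted_params, 10000, "T", f)
        np.testing.assert_allclose(s2.psd, 0.5 * s1.psd, rtol=1e-10)

    def test_refuses_limit_cycle_regime(self, limit_cycle_params):
        with pytest.raises(st.LNAValidityError):
            st.analytic_power_spectrum(limit_cycle_params, 5000)


class TestPeriodogram:
    def _sinusoid_traj(self, fitted_params, f0=0.04, dt=0.5, t_end=400.0):
        t = np.arange(0.0, t_end + dt / 2, dt)
        x = 1000 + 200 * np.sin(2 * np.pi * f0 * t)
        counts = np.zeros((t.size, 3), dtype=np.int64)
        counts[:, 0] = np.round(x)
        return st.Trajectory(time_hr=t, counts=counts, N_tot=5000,
                             params=fitted_params, seed=0)

    def test_sinusoid_peaks_at_its_frequency(self, fitted_params):
        traj = self._sinusoid_traj(fitted_params, f0=0.04)
        sp = st.periodogram_from_trajectory(traj, "T")
        assert sp.peak_freq_per_hr == pytest.approx(0.04, abs=1.5 / 400.0)

    def test_parseval(self, fitted_params):
        traj = self._sinusoid_traj(fitted_params)
        sp = st.periodogram_from_trajectory(traj, "T")
        x = traj.species_concentration("T")
        df = sp.freq_per_hr[1] - sp.freq_per_hr[0]
        assert np.sum(sp.psd) * df == pytest.approx(np.var(x), rel=1e-10)

    def test_too_short_trajectory_raises(self, fitted_params):
        traj = self._sinusoid_traj(fitted_params, t_end=50.0)
        with pytest.raises(ValueError):
            st.periodogram_from_trajectory(traj, "T")

    def test_averaged_ssa_periodograms_approach_analytic(self, circadian_focus_params):
        """Light SSA<->LNA check; the full equivalence is exercised at
        acceptance scale."""
        p = circadian_focus_params
        specs = [st.periodogram_from_trajectory(
            st.gillespie_single(p, 5000, 550.0, seed=600 + i), "T",
            discard_initial_hr=50.0) for i in range(15)]
        avg = st.average_spectra(specs)
        ana = st.analytic_power_spectrum(p, 5000, "T", avg.freq_per_hr)
        band = (avg.freq_per_hr >= 1 / 60) & (avg.freq_per_hr <= 1 / 10)
        r = np.corrcoef(np.log(avg.psd[band]), np.log(ana.psd[band]))[0, 1]
        assert r > 0.9
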