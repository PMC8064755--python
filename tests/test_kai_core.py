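"""Deterministic clock core: activity function, rate laws, fixed points,
stability classification and the Hopf scan."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_
from scipy.integrate import solve_ivp

from filaclock import kai_core as kc
from filaclock.params import (TRANSITIONS, KineticParams, ModelParams,
                              default_kinetics, default_params)


class TestActiveKaiA:
    def test_no_sequestration_without_S(self, fitted_params):
        A = kc.active_kaiA(0.0, fitted_params)
        assert A == pytest.approx(fitted_params.kaiA_total, rel=1e-2)

    def test_sharp_limit_saturates(self):
        p = default_params(gamma=1000.0)
        assert kc.active_kaiA(0.9 * p.kaiA_total, p) == pytest.approx(0.0, abs=1e-6)

    def test_converges_to_sharp_rule_with_gamma(self):
        """Sup-distance to max(0, kaiA - 2 S) decreases along gamma."""
        kin = default_kinetics()
        S = np.linspace(0.0, kin.C_tot, 301)
        errs = []
        for g in (10.0, 100.0, 1000.0):
            p = ModelParams(kinetics=kin, gamma=g, kaiA_total=1.3)
            sharp = np.maximum(0.0, p.kaiA_total - 2.0 * S)
            errs.append(np.max(np.abs(kc.active_kaiA(S, p) - sharp)))
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] < 1e-3

    def test_domain_errors(self, fitted_params):
        with pytest.raises(ValueError):
            kc.active_kaiA(-0.1, fitted_params)
        with pytest.raises(ValueError):
            kc.active_kaiA(fitted_params.C_tot + 0.1, fitted_params)

    @settings(max_examples=50, derandomize=True)
    @given(s=st_.floats(0.0, 3.4), g=st_.floats(0.5, 200.0))
    def test_monotone_nonincreasing_and_bounded(self, s, g):
        p = default_params(gamma=g)
        a1 = kc.active_kaiA(s, p)
        a2 = kc.active_kaiA(min(s + 0.05, p.C_tot), p)
        assert a2 <= a1 + 1e-12
        assert a1 >= 0.0

    def test_slope_matches_finite_difference(self, fitted_params):
        S = np.linspace(0.05, 3.0, 25)
        h = 1e-7
        fd = (kc.active_kaiA(S + h, fitted_params, check=False)
              - kc.active_kaiA(S - h, fitted_params, check=False)) / (2 * h)
        np.testing.assert_allclose(kc.activity_slope(S, fitted_params), fd,
                                   rtol=1e-6, atol=1e-9)


class TestRates:
    def test_limits_and_half_saturation(self, fitted_params):
        kin = fitted_params.kinetics
        for i, t in enumerate(TRANSITIONS):
            assert kc.rate(t, 0.0, fitted_params) == pytest.approx(kin.k0[i])
        # saturation limit and half-saturation on a KaiA-stimulated step
        i = TRANSITIONS.index("UT")
        assert kc.rate("UT", 1e9, fitted_params) == pytest.approx(
            kin.k0[i] + kin.kA[i], rel=1e-6)
        assert kc.rate("UT", kin.K_half, fitted_params) == pytest.approx(
            kin.k0[i] + kin.kA[i] / 2.0)

    def test_unknown_transition(self, fitted_params):
        with pytest.raises(KeyError):
            kc.rate("XZ", 1.0, fitted_params)

    def test_monotone_in_A_and_clamped(self, fitted_params):
        A = np.linspace(0.0, 10.0, 50)
        rates = np.array([kc.transition_rates(a, fitted_params.kinetics) for a in A])
        assert np.all(rates >= 0.0)
        kA = fitted_params.kinetics.kA
        for i in range(8):
            d = np.diff(rates[:, i])
            if kA[i] > 0:
                assert np.all(d >= -1e-12)
            elif kA[i] < 0:
                # non-increasing until (possibly) clamped at zero
                assert np.all(d <= 1e-12)


class TestOdeRhs:
    def test_matches_per_reaction_flux_assembly(self, fitted_params):
        """rhs equals the independent sum of the eight reaction fluxes, and
        total KaiC is conserved (the flux sum over U,T,D,S vanishes)."""
        from filaclock.params import SOURCE_SPECIES, STOICHIOMETRY
        rng = np.random.default_rng(0)
        for _ in range(10):
            y = rng.dirichlet([1, 1, 1, 1])[:3] * fitted_params.C_tot
            U = fitted_params.C_tot - y.sum()
            A = kc.active_kaiA(y[2], fitted_params, check=False)
            k = kc.transition_rates(A, fitted_params.kinetics)
            pools = np.array([U, y[0], y[1], y[2]])
            fluxes = k * pools[SOURCE_SPECIES]
            d_expected = fluxes @ STOICHIOMETRY.astype(float)
            np.testing.assert_allclose(kc.ode_rhs(y, fitted_params),
                                       d_expected, rtol=1e-12, atol=1e-14)
            # U balance closes the conservation law exactly
            dU = -fluxes[0] - fluxes[7] + fluxes[1] + fluxes[6]
            assert dU + d_expected.sum() == pytest.approx(0.0, abs=1e-13)

    def test_no_kaiA_gives_linear_system(self):
        """With [KaiA]=0 the rhs is linear with the basal-rate matrix."""
        p = default_params(kaiA_total=1e-12)
        kin = p.kinetics
        k = dict(zip(TRANSITIONS, kin.k0))
        M = np.array([
            [-k["UT"] - (k["TU"] + k["TD"]), -k["UT"] + k["DT"], -k["UT"]],
            [k["TD"], -(k["DT"] + k["DS"]), k["SD"]],
            [-k["US"], -k["US"] + k["DS"], -k["US"] - (k["SU"] + k["SD"])],
        ])
        b = np.array([k["UT"], 0.0, k["US"]]) * kin.C_tot
        rng = np.random.default_rng(1)
        for _ in range(5):
            y = rng.dirichlet([1, 1, 1, 1])[:3] * kin.C_tot
            np.testing.assert_allclose(kc.ode_rhs(y, p), M @ y + b,
                                       rtol=1e-9, atol=1e-12)

    def test_analytic_jacobian_vs_finite_difference(self, fitted_params):
        rng = np.random.default_rng(2)
        for _ in range(10):
            y = rng.dirichlet([1, 1, 1, 1])[:3] * fitted_params.C_tot
            J = kc.jacobian(y, fitted_params)
            Jfd = np.zeros((3, 3))
            f0 = kc.ode_rhs(y, fitted_params)
            h = 1e-7
            for j in range(3):
                yp = y.copy()
                yp[j] += h
                Jfd[:, j] = (kc.ode_rhs(yp, fitted_params) - f0) / h
            np.testing.assert_allclose(J, Jfd, rtol=1e-5,
                                       atol=1e-6 * np.abs(J).max())


class TestFixedPoint:
    def test_residual_below_tolerance(self, fitted_params):
        fp = kc.find_fixed_point(fitted_params)
        assert np.max(np.abs(kc.ode_rhs(fp.as_array(), fitted_params))) < 1e-10
        fp.validate()

    def test_no_kaiA_matches_linear_solve(self):
        # nonzero basal rates so the A=0 balance system is nondegenerate
        # (with the in vitro constants the A=0 fixed point is all-U)
        base = default_kinetics()
        kin = KineticParams(k0=base.k0 + 0.05, kA=base.kA,
                            K_half=base.K_half, C_tot=base.C_tot)
        p = ModelParams(kinetics=kin, gamma=7.2, kaiA_total=1e-12)
        k = dict(zip(TRANSITIONS, kin.k0))
        M = np.array([
            [-k["UT"] - (k["TU"] + k["TD"]), -k["UT"] + k["DT"], -k["UT"]],
            [k["TD"], -(k["DT"] + k["DS"]), k["SD"]],
            [-k["US"], -k["US"] + k["DS"], -k["US"] - (k["SU"] + k["SD"])],
        ])
        b = np.array([k["UT"], 0.0, k["US"]]) * kin.C_tot
        expected = np.linalg.solve(M, -b)
        fp = kc.find_fixed_point(p)
        np.testing.assert_allclose(fp.as_array(), expected, rtol=1e-8)

    def test_idempotent_under_perturbed_guesses(self, fitted_params):
        fp = kc.find_fixed_point(fitted_params).as_array()
        rng = np.random.default_rng(3)
        for _ in range(5):
            guess = fp * (1 + 0.2 * rng.standard_normal(3))
            fp2 = kc.find_fixed_point(fitted_params,
                                      initial_guess=np.clip(guess, 0.01, 3.3))
            np.testing.assert_allclose(fp2.as_array(), fp, atol=1e-8)

    def test_forward_integration_stays_at_fixed_point(self, circadian_focus_params):
        fp = kc.find_fixed_point(circadian_focus_params).as_array()
        sol = solve_ivp(lambda t, y: kc.ode_rhs(y, circadian_focus_params),
                        (0.0, 100.0), fp, rtol=1e-10, atol=1e-13)
        assert np.max(np.abs(sol.y[:, -1] - fp)) < 1e-6


class TestStability:
    def test_fitted_point_is_stable_focus(self, fitted_params):
        rep = kc.stability_and_period(fitted_params)
        assert rep.regime == "stable_focus"
        assert rep.max_re_lambda < 0
        assert 15.0 < rep.period_hr < 30.0   # quasi-cycle period 2*pi/|Im|

    def test_no_kaiA_is_stable_non_oscillatory(self):
        rep = kc.stability_and_period(default_params(kaiA_total=1e-12))
        assert rep.regime != "limit_cycle"
        assert rep.max_re_lambda < 0

    def test_limit_cycle_has_sustained_oscillation(self, limit_cycle_params):
        rep = kc.stability_and_period(limit_cycle_params)
        assert rep.regime == "limit_cycle"
        assert 20.0 < rep.period_hr < 30.0
        period, decay = kc.measure_ode_period(limit_cycle_params,
                                              transient_hr=300.0, run_hr=10 * 25.0)
        assert abs(decay) < 0.01   # amplitude decay < 1% per period


class TestHopfScan:
    @pytest.fixture(scope="class")
    def scan(self):
        return kc.hopf_scan(np.linspace(2.0, 30.0, 8),
                            np.linspace(0.6, 2.0, 8))

    def test_fitted_point_outside_limit_cycle_region(self):
        df = kc.hopf_scan([7.2], [1.308])
        assert df.iloc[0].regime == "stable_focus"

    def test_contains_both_regimes(self, scan):
        assert (scan.regime == "limit_cycle").any()
        assert scan.regime.isin(["stable_focus", "stable_node"]).any()

    def test_pointwise_independence(self, scan):
        """The map is identical when the grid is traversed in another order."""
        sub = kc.hopf_scan([30.0, 2.0], [2.0, 0.6])
        for _, row in sub.iterrows():
            match = scan[(scan.gamma == row.gamma) & (scan.kaiA == row.kaiA)]
            assert match.iloc[0].regime == row.regime
            assert match.iloc[0].max_re_lambda == pytest.approx(
                row.max_re_lambda, rel=1e-12)

    def test_boundary_crossing_is_sharp(self, scan):
        """Along a kaiA column, the regime flips where max Re crosses zero."""
        col = scan[scan.kaiA == scan.kaiA.iloc[1]].sort_values("gamma")
        sign = np.sign(col.max_re_lambda.to_numpy())
        regimes = (col.regime == "limit_cycle").to_numpy()
        np.testing.assert_array_equal(regimes, sign > 0)
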