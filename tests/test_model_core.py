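"""GI/GIG right-hand sides, reference integration, and nesting."""

import numpy as np
import pytest
from dataclasses import replace
from scipy.linalg import expm

from glucoclamp import fastsim, units
from glucoclamp.errors import DomainError
from glucoclamp.model_core import (ClampProtocol, GIGParameters, fasting_state,
                                   gi_rhs, gig_rhs, simulate)


class TestGIRHS:
    def test_glucose_steady_state_identity(self, gi_params, zero_protocol):
        """With no infusions and no insulin, Gc = k1/(k2+k8) is stationary."""
        p = gi_params
        gc = p.k1 / (p.k2 + p.k8)
        d = gi_rhs((gc, gc, 0.0), 10.0, p, zero_protocol)
        assert d[0] == pytest.approx(0.0, abs=1e-14)

    def test_y_tracks_constant_glucose(self, gi_params, zero_protocol):
        d = gi_rhs((7.0, 7.0, 50.0), 0.0, gi_params, zero_protocol)
        assert d[1] == 0.0

    def test_below_threshold_secretion_is_zero(self, gi_params,
                                               infused_protocol):
        p = gi_params
        state = (3.0, p.k6 - 1.0, 40.0)  # Y below threshold
        d = gi_rhs(state, 0.0, p, infused_protocol)
        assert d[2] == pytest.approx(
            infused_protocol.insulin_flux(0.0) - p.k7 * 40.0)

    @pytest.mark.parametrize("state,t", [((-1.0, 5.0, 10.0), 0.0),
                                         ((5.0, 5.0, 10.0), 200.0)])
    def test_domain_errors(self, gi_params, zero_protocol, state, t):
        with pytest.raises(DomainError):
            gi_rhs(state, t, gi_params, zero_protocol)


class TestGIGRHS:
    def test_glucagon_steady_state(self, gig_params, zero_protocol):
        p = gig_params
        i = 60.0
        gg = (p.kGgS / p.kGgC) / i
        d = gig_rhs((7.0, 7.0, i, gg, 0.5), 0.0, p, zero_protocol)
        assert d[3] == pytest.approx(0.0, abs=1e-12)

    def test_nests_gi_when_glucagon_action_removed(self, gig_params,
                                                   infused_protocol):
        """kGN = 0 makes the glucose equation identical to the GI model."""
        p = replace(gig_params, kGN=0.0)
        gi = p.to_gi()
        state = (6.0, 5.5, 80.0, 150.0, 0.6)
        d_gig = gig_rhs(state, 3.0, p, infused_protocol)
        d_gi = gi_rhs(state[:3], 3.0, gi, infused_protocol)
        assert d_gig[0] == pytest.approx(d_gi[0], rel=1e-15)
        assert d_gig[1] == pytest.approx(d_gi[1], rel=1e-15)
        assert d_gig[2] == pytest.approx(d_gi[2], rel=1e-15)

    def test_insulin_cpeptide_secretion_symmetry(self, gig_params,
                                                 zero_protocol):
        """With kratio=1 and kCPC=k7, posthepatic insulin mirrors
        C-peptide (in matched molar units) for all time."""
        p = replace(gig_params, kratio=1.0, kCPC=gig_params.k7)
        cp0 = 0.4
        y0 = [7.5, 7.5, units.PMOL_PER_NMOL * cp0, 150.0, cp0]
        traj = simulate("GIG", p, zero_protocol, y0, np.arange(0.0, 121.0))
        np.testing.assert_allclose(traj.I, units.PMOL_PER_NMOL * traj.CP,
                                   rtol=1e-7)


class TestSimulate:
    def test_steady_state_stays_constant(self, gig_params, zero_protocol):
        y0 = fasting_state(gig_params, "GIG")
        traj = simulate("GIG", gig_params, zero_protocol, y0,
                        np.arange(0.0, 121.0))
        for arr, ref in zip((traj.Gc, traj.I, traj.Gg, traj.CP),
                            (y0[0], y0[2], y0[3], y0[4])):
            np.testing.assert_allclose(arr, ref, rtol=1e-6)

    def test_linear_regime_matches_matrix_exponential(self, gi_params,
                                                      infused_protocol):
        """With X forced to zero and k4 = 0 the system is linear; the
        trajectory must match the closed-form affine-ODE solution."""
        p = replace(gi_params, k4=0.0, k6=1e6)  # X = max(Y - k6, 0) = 0
        proto = infused_protocol
        A = np.array([[-(p.k2 + p.k8), 0.0, 0.0],
                      [p.k3, -p.k3, 0.0],
                      [0.0, 0.0, -p.k7]])
        b = np.array([proto.glucose_flux(0.0) + p.k1, 0.0,
                      proto.insulin_flux(0.0)])
        y0 = np.array([4.0, 4.0, 30.0])
        t_grid = np.arange(0.0, 121.0)
        traj = simulate("GI", p, proto, y0, t_grid)
        sim = np.vstack([traj.Gc, traj.Y, traj.I])
        for i, t in enumerate(t_grid):
            eat = expm(A * t)
            ref = eat @ y0 + np.linalg.solve(A, (eat - np.eye(3)) @ b)
            np.testing.assert_allclose(sim[:, i], ref, rtol=1e-6, atol=1e-9)

    def test_infusion_doubling_doubles_deviation(self, gi_params):
        """With no insulin action/secretion the glucose response is
        linear in the infusion; closed form: u/(k2+k8)(1 - e^-(k2+k8)t)."""
        p = replace(gi_params, k4=0.0, k5=0.0)
        base = p.k1 / (p.k2 + p.k8)
        t_grid = np.arange(0.0, 121.0)
        devs = []
        for f1 in (1.0, 2.0):
            proto = ClampProtocol(120.0, np.full(121, f1), np.zeros(121),
                                  5.2, 65.0, 48.75)
            traj = simulate("GI", p, proto, [base, base, 0.0], t_grid)
            u = proto.glucose_flux(0.0)
            k = p.k2 + p.k8
            ref = base + u / k * (1.0 - np.exp(-k * t_grid))
            np.testing.assert_allclose(traj.Gc, ref, rtol=1e-6)
            devs.append(traj.Gc - base)
        np.testing.assert_allclose(devs[1], 2.0 * devs[0], rtol=1e-6,
                                   atol=1e-9)

    def test_gig_with_zero_kgn_reproduces_gi(self, gig_params,
                                             infused_protocol):
        p = replace(gig_params, kGN=0.0)
        y0 = fasting_state(p, "GIG")
        t_grid = np.arange(0.0, 121.0)
        gig = simulate("GIG", p, infused_protocol, y0, t_grid,
                       rtol=1e-11, atol=1e-12)
        gi = simulate("GI", p.to_gi(), infused_protocol, y0[:3], t_grid,
                      rtol=1e-11, atol=1e-12)
        np.testing.assert_allclose(gig.Gc, gi.Gc, rtol=1e-8)
        np.testing.assert_allclose(gig.I, gi.I, rtol=1e-8)

    def test_steady_glucose_decreases_with_urinary_excretion(self, gi_params):
        """With secretion off, steady-state Gc = k1/(k2+k8) falls as k8
        rises."""
        p = replace(gi_params, k5=0.0)
        previous = np.inf
        for k8 in (0.0, 0.005, 0.02, 0.1):
            g = fasting_state(replace(p, k8=k8), "GI")[0]
            assert g == pytest.approx(p.k1 / (p.k2 + k8))
            assert g < previous
            previous = g

    def test_invalid_inputs_raise(self, gi_params, zero_protocol):
        with pytest.raises(DomainError):
            simulate("XX", gi_params, zero_protocol, [1, 1, 1], [0, 1])
        with pytest.raises(DomainError):
            simulate("GI", gi_params, zero_protocol, [1, 1], [0, 1])
        with pytest.raises(DomainError):
            simulate("GI", gi_params, zero_protocol, [1, 1, 1], [0, 500.0])


class TestFastIntegrator:
    def test_matches_reference_solver_in_physiologic_regime(
            self, gig_params, infused_protocol):
        y0 = fasting_state(gig_params, "GIG")
        g_in, i_in = infused_protocol.flux_arrays()
        theta = np.array([[getattr(gig_params, k) for k in fastsim.GIG_ORDER]])
        fast = fastsim.integrate_gig_batch(theta, g_in, i_in, y0, 120, 1500.0)
        ref = simulate("GIG", gig_params, infused_protocol, y0,
                       np.arange(0.0, 121.0))
        for got, want in zip(fast, (ref.Gc, ref.Y, ref.I, ref.Gg, ref.CP)):
            np.testing.assert_allclose(
                got[0], want, rtol=2e-3,
                atol=2e-3 * max(np.max(np.abs(want)), 1.0))

    def test_numpy_and_numba_paths_agree(self, gi_params, infused_protocol):
        from glucoclamp.fastsim import (_rk4_gi_numpy, _rk4_gi_kernel,
                                        HAVE_NUMBA)
        if not HAVE_NUMBA:
            pytest.skip("single implementation in use")
        g_in, i_in = infused_protocol.flux_arrays()
        theta = np.array([[getattr(gi_params, k) for k in fastsim.GI_ORDER]])
        y0 = np.array([[7.0, 7.0, 50.0]])
        a = np.empty((1, 3, 121))
        b = np.empty((1, 3, 121))
        _rk4_gi_kernel(theta, g_in, i_in, y0, 120, 1, 1e7, a)
        _rk4_gi_numpy(theta, g_in, i_in, y0, 120, 1, 1e7, b)
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_wild_candidates_stay_finite(self, infused_protocol):
        g_in, i_in = infused_protocol.flux_arrays()
        rng = np.random.default_rng(0)
        theta = 10.0 ** rng.uniform(-4, 6, size=(50, 13))
        theta[:, 11] = np.minimum(theta[:, 11], 1.0)  # kratio <= 1
        out = fastsim.integrate_gig_batch(theta, g_in, i_in,
                                          [7.0, 7.0, 50.0, 150.0, 0.5],
                                          120, 1500.0)
        for arr in out:
            assert np.all(np.isfinite(arr))
            assert np.all(arr >= 0.0)
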