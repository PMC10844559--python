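"""Constitutive-law oracles: energies, stresses, and the viscous integrator."""

import numpy as np
import pytest

from viscofit.constitutive import (
    ALPHA_SMALL,
    InvalidParameterError,
    MaterialParameters,
    ViscousState,
    bulk_modulus,
    evaluate_stress,
    ogden_iso_energy,
    ogden_vol_energy,
    principal_kirchhoff,
    viscous_update,
)


def random_stretches(rng, n):
    """Random moderate principal-stretch triples."""
    return np.exp(rng.uniform(-0.3, 0.3, size=(n, 3)))


class TestBulkModulus:
    @pytest.mark.parametrize(
        "mu, nu, expected",
        [(162.0, 0.45, 1566.0), (0.0, 0.45, 0.0), (3.0, 0.0, 2.0)],
    )
    def test_values(self, mu, nu, expected):
        assert bulk_modulus(mu, nu) == pytest.approx(expected, rel=1e-12)

    def test_incompressible_limit_rejected(self):
        with pytest.raises(InvalidParameterError):
            bulk_modulus(100.0, 0.5)
        with pytest.raises(InvalidParameterError):
            bulk_modulus(-1.0, 0.3)


class TestOgdenEnergies:
    def test_undeformed_iso_energy_zero(self):
        assert ogden_iso_energy([1, 1, 1], mu=123.0, alpha=-7.0) == 0.0

    def test_uniaxial_isochoric_value(self):
        lb = (2.0, 2**-0.5, 2**-0.5)
        # (2 mu / alpha^2)(lam^2 + 2/lam - 3) at mu=1, alpha=2, lam=2 -> 1.0
        assert ogden_iso_energy(lb, mu=1.0, alpha=2.0) == pytest.approx(1.0, rel=1e-12)

    def test_small_alpha_limit(self, rng):
        lb = random_stretches(rng, 1)[0]
        lb /= np.prod(lb) ** (1 / 3)
        limit = 100.0 * np.sum(np.log(lb) ** 2)
        assert ogden_iso_energy(lb, 100.0, 1e-6) == pytest.approx(limit, rel=1e-6)

    def test_branch_continuity_at_threshold(self, rng):
        lb = random_stretches(rng, 1)[0]
        lb /= np.prod(lb) ** (1 / 3)
        for sign in (+1, -1):
            below = ogden_iso_energy(lb, 50.0, sign * ALPHA_SMALL * (1 - 1e-9))
            above = ogden_iso_energy(lb, 50.0, sign * ALPHA_SMALL * (1 + 1e-9))
            assert below == pytest.approx(above, rel=1e-8)
            tau_b = principal_kirchhoff(lb, 50.0, sign * ALPHA_SMALL * (1 - 1e-9), 100.0)
            tau_a = principal_kirchhoff(lb, 50.0, sign * ALPHA_SMALL * (1 + 1e-9), 100.0)
            assert np.max(np.abs(tau_b - tau_a)) < 1e-8 * np.max(np.abs(tau_a))

    def test_vol_energy_reference_state(self):
        assert ogden_vol_energy(1.0, kappa=1566.0) == 0.0
        with pytest.raises(InvalidParameterError):
            ogden_vol_energy(-0.1, 1.0)

    def test_vol_energy_curvature(self):
        # stress-free reference: dPsi/dJ = 0 at J=1; d2Psi/dJ2 = kappa
        kappa, h = 777.0, 1e-5
        d1 = (ogden_vol_energy(1 + h, kappa) - ogden_vol_energy(1 - h, kappa)) / (2 * h)
        d2 = (
            ogden_vol_energy(1 + h, kappa) - 2 * ogden_vol_energy(1.0, kappa) + ogden_vol_energy(1 - h, kappa)
        ) / h**2
        assert abs(d1) < 1e-6 * kappa
        assert d2 == pytest.approx(kappa, rel=1e-4)

    def test_vol_energy_nonnegative(self, rng):
        for J in np.exp(rng.uniform(-0.5, 0.5, 20)):
            assert ogden_vol_energy(J, 100.0) >= 0.0


class TestPrincipalKirchhoff:
    def test_undeformed_stress_free(self):
        assert np.allclose(principal_kirchhoff([1, 1, 1], 200.0, -15.0, 1000.0), 0.0)

    def test_isochoric_stress_deviatoric(self):
        tau = principal_kirchhoff([1.1, 1 / 1.1, 1.0], mu=1.0, alpha=2.0, kappa=50.0)
        assert abs(tau.sum()) < 1e-12

    @pytest.mark.parametrize("alpha", [2.0, -15.0, 1e-6])
    def test_matches_energy_gradient(self, rng, alpha):
        """Stress equals the numerical gradient of the total energy w.r.t.
        the logarithmic principal stretches (100 random states)."""
        mu, kappa = 150.0, 900.0
        h = 1e-6
        for lam in random_stretches(rng, 100):
            tau = principal_kirchhoff(lam, mu, alpha, kappa)

            def energy(eps):
                lam_e = np.exp(eps)
                J = np.prod(lam_e)
                lb = lam_e / J ** (1 / 3)
                return ogden_iso_energy(lb, mu, alpha) + ogden_vol_energy(J, kappa)

            eps0 = np.log(lam)
            num = np.empty(3)
            for a in range(3):
                ep, em = eps0.copy(), eps0.copy()
                ep[a] += h
                em[a] -= h
                num[a] = (energy(ep) - energy(em)) / (2 * h)
            scale = max(np.max(np.abs(num)), 1.0)
            assert np.max(np.abs(tau - num)) / scale < 1e-5


def shear_F(gamma):
    F = np.eye(3)
    F[0, 1] = gamma
    return F


class TestViscousUpdate:
    def test_frozen_dashpot_limit(self, rng):
        """With a huge viscosity the branch behaves as an elastic spring:
        b_e tracks the (trial) total deformation."""
        p = MaterialParameters(100.0, 2.0, 200.0, 2.0, 1e12 * 200.0 * 0.1)
        F = shear_F(0.3)
        state, tau = viscous_update(ViscousState(), np.eye(3), F, 0.1, p)
        assert np.allclose(state.b_e, F @ F.T, atol=1e-9)
        lam2, _ = np.linalg.eigh(F @ F.T)
        expected = principal_kirchhoff(np.sqrt(lam2), 200.0, 2.0, p.kappa_1)
        got, _ = np.linalg.eigh(tau)
        assert np.allclose(np.sort(got), np.sort(expected), atol=1e-8 * 200.0)

    def test_linear_maxwell_relaxation(self):
        """Small step shear then hold: tau_12(t) = mu1 gamma0 exp(-t mu1/eta1)
        to within 1%."""
        mu1, eta1 = 200.0, 400.0
        p = MaterialParameters(100.0, 2.0, mu1, 2.0, eta1)
        gamma0, dt = 1e-4, 0.01
        F = shear_F(gamma0)
        state, tau = viscous_update(ViscousState(), np.eye(3), F, dt, p)
        t = dt
        for _ in range(400):
            exact = mu1 * gamma0 * np.exp(-t * mu1 / eta1)
            assert tau[0, 1] == pytest.approx(exact, rel=0.01)
            state, tau = viscous_update(state, F, F, dt, p)
            t += dt

    def test_first_order_timestep_convergence(self, params):
        """Halving the step roughly halves the deviation from a fine-step
        reference along a ramp trajectory."""

        def run(nsub):
            state = ViscousState()
            gammas = np.linspace(0, 0.2, 10 * nsub + 1)
            tau = None
            for g_old, g_new in zip(gammas[:-1], gammas[1:]):
                state, tau = viscous_update(state, shear_F(g_old), shear_F(g_new), 0.1 / nsub, params)
            return tau[0, 1]

        ref = run(64)
        err_coarse = abs(run(1) - ref)
        err_half = abs(run(2) - ref)
        assert err_half < 0.7 * err_coarse

    def test_viscous_volume_preserved(self, params, rng):
        """det F_v = det F / sqrt(det b_e) stays 1 along a random trajectory."""
        state = ViscousState()
        F_old = np.eye(3)
        for _ in range(30):
            F_new = F_old + 0.02 * rng.standard_normal((3, 3))
            if np.linalg.det(F_new) <= 0.1:
                continue
            state, _ = viscous_update(state, F_old, F_new, 0.05, params)
            det_Fv = np.linalg.det(F_new) / np.sqrt(np.linalg.det(state.b_e))
            assert det_Fv == pytest.approx(1.0, abs=1e-8)
            F_old = F_new

    def test_dissipation_nonnegative_over_cycle(self, params):
        """Net work of the Maxwell branch over a closed small-strain shear
        cycle is dissipative (>= 0)."""
        n = 200
        gam = 1e-3 * np.sin(2 * np.pi * np.arange(n + 1) / n)
        state = ViscousState()
        work = 0.0
        for g_old, g_new in zip(gam[:-1], gam[1:]):
            state, tau = viscous_update(state, shear_F(g_old), shear_F(g_new), 0.01, params)
            work += tau[0, 1] * (g_new - g_old)
        assert work >= 0.0

    def test_invalid_dt(self, params):
        with pytest.raises(InvalidParameterError):
            viscous_update(ViscousState(), np.eye(3), np.eye(3), 0.0, params)


class TestEvaluateStress:
    def test_reference_state_stress_free(self, params):
        sigma, _ = evaluate_stress(np.eye(3), ViscousState(), 0.1, params)
        assert np.allclose(sigma, 0.0)

    def test_instantaneous_and_equilibrium_shear_moduli(self):
        mu_inf, mu1, eta1 = 100.0, 200.0, 400.0
        p = MaterialParameters(mu_inf, 2.0, mu1, 2.0, eta1)
        gamma, dt = 1e-5, 1e-4
        sigma, state = evaluate_stress(shear_F(gamma), ViscousState(), dt, p)
        assert sigma[0, 1] / gamma == pytest.approx(mu_inf + mu1, rel=0.01)
        # hold until t >> eta/mu
        for _ in range(int(20 * eta1 / mu1 / 0.05)):
            sigma, state = evaluate_stress(shear_F(gamma), state, 0.05, p)
        assert sigma[0, 1] / gamma == pytest.approx(mu_inf, rel=0.01)

    def test_objectivity_under_superposed_rotation(self, params, rng):
        """sigma(Q F) = Q sigma(F) Q^T for a random constant rotation."""
        A = rng.standard_normal((3, 3))
        Q, _ = np.linalg.qr(A)
        Q *= np.linalg.det(Q)  # proper rotation
        F = np.eye(3) + 0.1 * rng.standard_normal((3, 3))
        assert np.linalg.det(F) > 0
        sigma, _ = evaluate_stress(F, ViscousState(), 0.1, params)
        sigma_rot, _ = evaluate_stress(Q @ F, ViscousState(), 0.1, params)
        assert np.allclose(sigma_rot, Q @ sigma @ Q.T, atol=1e-8 * params.mu_inf)

    def test_stress_symmetric(self, params, rng):
        F = np.eye(3) + 0.15 * rng.standard_normal((3, 3))
        sigma, _ = evaluate_stress(F, ViscousState(), 0.1, params)
        assert np.allclose(sigma, sigma.T)


class TestMaterialParameters:
    def test_derived_bulk_moduli(self):
        p = MaterialParameters(162.0, -16.0, 398.0, -18.0, 13949.0)
        assert p.kappa_inf == pytest.approx(bulk_modulus(162.0, 0.45))
        assert p.kappa_1 == pytest.approx(bulk_modulus(398.0, 0.45))

    def test_array_roundtrip(self, params):
        assert MaterialParameters.from_array(params.as_array()) == params

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(mu_inf=-1.0),
            dict(eta_1=0.0),
            dict(nu=0.5),
            dict(mu_1=-5.0),
        ],
    )
    def test_invalid_rejected(self, kwargs):
        base = dict(mu_inf=100.0, alpha_inf=2.0, mu_1=50.0, alpha_1=2.0, eta_1=10.0)
        with pytest.raises(InvalidParameterError):
            MaterialParameters(**{**base, **kwargs})
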