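"""Finite-strain viscoelastic constitutive law at a material point.

The model is a generalized Maxwell network: a compressible one-term Ogden
spring carrying the equilibrium response, in parallel with a single Maxwell
branch (one-term Ogden spring in series with a purely deviatoric dashpot).
Kinematics use the multiplicative split ``F = F_e @ F_v`` of the deformation
gradient into an elastic and a viscous part; the internal variable is the
elastic left Cauchy-Green tensor ``b_e = F_e @ F_e.T`` of the Maxwell branch.

Stresses are evaluated in principal logarithmic strains, and the internal
variable is advanced with the standard exponential-map predictor-corrector
(trial ``b_e`` pushed forward by the incremental deformation, then a local
Newton return in principal log-strain space).  Because the dashpot flows
only deviatorically, the viscous part is exactly volume-preserving.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ALPHA_SMALL",
    "InvalidParameterError",
    "IntegrationError",
    "MaterialParameters",
    "ViscousState",
    "bulk_modulus",
    "ogden_iso_energy",
    "ogden_vol_energy",
    "principal_kirchhoff",
    "viscous_update",
    "evaluate_stress",
]

#: Below this |alpha| the Ogden terms switch to their alpha -> 0 series limit
#: (alpha**2 appears in denominators, so the direct form loses all precision).
ALPHA_SMALL = 1e-4

#: Local Newton settings for the viscous return mapping (residual measured in
#: principal logarithmic strain).
NEWTON_TOL = 1e-10
NEWTON_MAXIT = 50

#: Names and order of the five free parameters wherever they appear as a
#: flat vector (sampling boxes, optimizer variables, surrogate inputs).
PARAM_NAMES = ("mu_inf", "alpha_inf", "mu_1", "alpha_1", "eta_1")


class InvalidParameterError(ValueError):
    """Raised for physically inadmissible material parameters."""


class IntegrationError(RuntimeError):
    """Raised when the local Newton of the viscous update fails to converge."""

    def __init__(self, message: str, residual: float = np.nan):
        super().__init__(message)
        self.residual = residual


def bulk_modulus(mu: float, nu: float) -> float:
    """Bulk modulus from shear modulus and Poisson ratio (linear regime).

    ``kappa = 2 mu (1 + nu) / (3 (1 - 2 nu))``.  The incompressible limit
    ``nu >= 0.5`` is rejected; use values strictly below one half.
    """
    if mu < 0:
        raise InvalidParameterError(f"shear modulus must be >= 0, got {mu}")
    if not 0 <= nu < 0.5:
        raise InvalidParameterError(f"Poisson ratio must be in [0, 0.5), got {nu}")
    return mu * 2.0 * (1.0 + nu) / (3.0 * (1.0 - 2.0 * nu))


@dataclass(frozen=True)
class MaterialParameters:
    """The five free constitutive parameters plus the fixed Poisson ratio.

    ``mu_inf``/``alpha_inf`` characterize the equilibrium Ogden spring,
    ``mu_1``/``alpha_1`` the Maxwell spring and ``eta_1`` the (deviatoric)
    dashpot viscosity.  Bulk moduli are not free: each spring derives its
    own ``kappa`` from its shear modulus and the shared Poisson ratio.
    """

    mu_inf: float  # Pa
    alpha_inf: float  # -
    mu_1: float  # Pa
    alpha_1: float  # -
    eta_1: float  # Pa s
    nu: float = 0.45  # -

    def __post_init__(self) -> None:
        if self.mu_inf <= 0:
            raise InvalidParameterError(f"mu_inf must be > 0, got {self.mu_inf}")
        if self.mu_1 < 0:
            raise InvalidParameterError(f"mu_1 must be >= 0, got {self.mu_1}")
        if self.eta_1 <= 0:
            raise InvalidParameterError(f"eta_1 must be > 0, got {self.eta_1}")
        bulk_modulus(1.0, self.nu)  # validates nu

    @property
    def kappa_inf(self) -> float:
        return bulk_modulus(self.mu_inf, self.nu)

    @property
    def kappa_1(self) -> float:
        return bulk_modulus(self.mu_1, self.nu)

    def as_array(self) -> np.ndarray:
        """The free parameters as a vector in ``PARAM_NAMES`` order."""
        return np.array(
            [self.mu_inf, self.alpha_inf, self.mu_1, self.alpha_1, self.eta_1]
        )

    @classmethod
    def from_array(cls, theta, nu: float = 0.45) -> "MaterialParameters":
        mu_inf, alpha_inf, mu_1, alpha_1, eta_1 = (float(v) for v in theta)
        return cls(mu_inf, alpha_inf, mu_1, alpha_1, eta_1, nu=nu)


@dataclass
class ViscousState:
    """Internal state of the Maxwell branch carried across time steps.

    ``b_e`` is the elastic left Cauchy-Green tensor of the branch; ``F`` is
    the total deformation gradient at the last converged step, needed to form
    the incremental deformation of the next step.
    """

    b_e: np.ndarray = field(default_factory=lambda: np.eye(3))
    F: np.ndarray = field(default_factory=lambda: np.eye(3))

    def copy(self) -> "ViscousState":
        return ViscousState(self.b_e.copy(), self.F.copy())


def ogden_iso_energy(lambda_bar, mu: float, alpha: float) -> float:
    """Isochoric one-term Ogden energy ``(2 mu / alpha^2) (sum lb^alpha - 3)``.

    ``lambda_bar`` are the three isochoric principal stretches (product one).
    For ``|alpha| < ALPHA_SMALL`` the analytic limit ``mu * sum(log lb)^2``
    is used.
    """
    lb = np.asarray(lambda_bar, dtype=float)
    if np.any(lb <= 0):
        raise InvalidParameterError("isochoric stretches must be positive")
    e = np.log(lb)
    if abs(alpha) < ALPHA_SMALL:
        # series limit with first-order correction, continuous at the switch
        return float(mu * (np.sum(e**2) + alpha / 3.0 * np.sum(e**3)))
    # expm1 form avoids the catastrophic cancellation of sum(lb^alpha) - 3
    return float(2.0 * mu / alpha**2 * np.sum(np.expm1(alpha * e)))


def ogden_vol_energy(J: float, kappa: float) -> float:
    """Volumetric energy ``(kappa / 4) (J^2 - 1 - 2 log J)``; zero iff J=1."""
    if J <= 0:
        raise InvalidParameterError(f"volume ratio must be positive, got {J}")
    return float(kappa / 4.0 * (J**2 - 1.0 - 2.0 * np.log(J)))


def _iso_tau_principal(eps: np.ndarray, mu: float, alpha: float) -> np.ndarray:
    """Isochoric principal Kirchhoff stresses from principal log stretches.

    ``eps`` holds log of the principal stretches; only its deviatoric part
    enters.  The three returned stresses sum to zero identically.
    """
    e = eps - eps.mean()
    if abs(alpha) < ALPHA_SMALL:
        # second-order series, continuous at the branch switch to O(alpha^3)
        e2 = e**2 - np.mean(e**2)
        e3 = e**3 - np.mean(e**3)
        return 2.0 * mu * (e + 0.5 * alpha * e2 + alpha**2 / 6.0 * e3)
    x = np.expm1(alpha * e)
    return (2.0 * mu / alpha) * (x - x.mean())


def _iso_tau_jacobian(eps: np.ndarray, mu: float, alpha: float) -> np.ndarray:
    """d tau_iso_a / d eps_b for the return-mapping Newton."""
    P = np.eye(3) - 1.0 / 3.0
    if abs(alpha) < ALPHA_SMALL:
        return 2.0 * mu * P
    e = eps - eps.mean()
    x = np.exp(alpha * e)
    return 2.0 * mu * (x[:, None] * P - (x[None, :] - x.mean()) / 3.0)


def principal_kirchhoff(lam, mu: float, alpha: float, kappa: float) -> np.ndarray:
    """Principal Kirchhoff stresses of one compressible Ogden spring.

    ``lam`` are the spring's principal stretches.  The stress is the
    derivative of the isochoric plus volumetric energy with respect to the
    logarithmic principal stretches:

    ``tau_a = (2 mu / alpha) (lb_a^alpha - mean(lb^alpha)) + (kappa/2)(J^2-1)``
    """
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise InvalidParameterError("principal stretches must be positive")
    eps = np.log(lam)
    J = float(np.exp(eps.sum()))
    return _iso_tau_principal(eps, mu, alpha) + 0.5 * kappa * (J**2 - 1.0)


def _spectral(A: np.ndarray):
    """Eigen-decomposition of a symmetric 3x3 with symmetrization guard."""
    w, V = np.linalg.eigh(0.5 * (A + A.T))
    return w, V


def viscous_update(
    state: ViscousState,
    F_old: np.ndarray,
    F_new: np.ndarray,
    dt: float,
    params: MaterialParameters,
):
    """Advance the Maxwell branch over one time step.

    Exponential-map predictor-corrector: the trial elastic tensor is the old
    ``b_e`` pushed forward by the incremental deformation
    ``f = F_new @ inv(F_old)``; the corrector solves, in principal
    logarithmic elastic strains,

        ``eps_a = eps_trial_a - dt / (2 eta_1) * dev tau_a(eps)``

    by a local Newton (the deviatoric flow rule with the volumetric dashpot
    disabled).  Returns the updated state and the branch Kirchhoff stress.
    """
    if dt <= 0:
        raise InvalidParameterError(f"dt must be positive, got {dt}")
    f = F_new @ np.linalg.inv(F_old)
    b_tr = f @ state.b_e @ f.T
    w, V = _spectral(b_tr)
    if np.any(w <= 0):
        raise IntegrationError("trial elastic tensor not positive definite")
    eps_tr = 0.5 * np.log(w)

    c = dt / (2.0 * params.eta_1)
    mu, alpha = params.mu_1, params.alpha_1
    eps = eps_tr.copy()
    resid = np.inf
    for _ in range(NEWTON_MAXIT):
        r = eps - eps_tr + c * _iso_tau_principal(eps, mu, alpha)
        resid = float(np.max(np.abs(r)))
        if resid < NEWTON_TOL:
            break
        Jac = np.eye(3) + c * _iso_tau_jacobian(eps, mu, alpha)
        eps = eps - np.linalg.solve(Jac, r)
    else:
        raise IntegrationError(
            f"viscous return mapping did not converge (residual {resid:.3e})",
            residual=resid,
        )

    Je = float(np.exp(eps.sum()))
    tau_p = _iso_tau_principal(eps, mu, alpha) + 0.5 * params.kappa_1 * (Je**2 - 1.0)
    b_e = (V * np.exp(2.0 * eps)) @ V.T
    tau_neq = (V * tau_p) @ V.T
    new_state = ViscousState(b_e=0.5 * (b_e + b_e.T), F=np.asarray(F_new, float).copy())
    return new_state, 0.5 * (tau_neq + tau_neq.T)


def evaluate_stress(
    F: np.ndarray,
    state: ViscousState,
    dt: float,
    params: MaterialParameters,
):
    """Total Cauchy stress at deformation ``F`` one step after ``state``.

    The equilibrium spring is evaluated directly on the principal stretches
    of ``F``; the Maxwell branch is advanced from ``state`` (whose ``F``
    field is the previous step's deformation).  Returns ``(sigma, new_state)``
    with ``sigma = (tau_eq + tau_neq) / J``.  ``state`` is not mutated, so a
    trial evaluation can be discarded.
    """
    F = np.asarray(F, dtype=float)
    J = float(np.linalg.det(F))
    if J <= 0:
        raise InvalidParameterError(f"det(F) must be positive, got {J}")
    w, V = _spectral(F @ F.T)
    lam = np.sqrt(np.clip(w, 0.0, None))
    tau_eq_p = principal_kirchhoff(lam, params.mu_inf, params.alpha_inf, params.kappa_inf)
    tau_eq = (V * tau_eq_p) @ V.T

    new_state, tau_neq = viscous_update(state, state.F, F, dt, params)
    sigma = (tau_eq + tau_neq) / J
    return 0.5 * (sigma + sigma.T), new_state
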