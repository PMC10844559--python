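"""Homogeneous material-point simulation of combined compression-tension
and torsional shear.

This is the high-fidelity labeler of the pipeline: it maps a loading
protocol — axial stretch ``lambda(t)`` and amount of shear ``gamma(t)`` on a
uniform time grid — plus a set of material parameters to the measured stress
channels, the nominal (first Piola) axial stress ``P(t)`` and the Cauchy
shear stress ``tau(t)``.  The specimen is treated as a single homogeneous
material point with a traction-free lateral surface: at every time step the
lateral stretch is solved so that the radial Cauchy stress vanishes.

The deformation gradient combines an axial stretch, an equal lateral
stretch in both transverse directions, and a superposed simple shear in the
theta-z plane (the homogenized kinematics of a twisted cylinder at its
effective radius):

    ``F = (I + gamma e_y o e_z) @ diag(l, l, lambda_ax)``
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constitutive import (
    IntegrationError,
    InvalidParameterError,
    MaterialParameters,
    ViscousState,
    evaluate_stress,
)

__all__ = [
    "LoadingProtocol",
    "StressResponse",
    "SimulationError",
    "build_deformation_gradient",
    "solve_lateral_stretch",
    "simulate_response",
]


class SimulationError(RuntimeError):
    """Raised when the per-step lateral-stretch solve or integrator fails."""


@dataclass(frozen=True)
class LoadingProtocol:
    """Imposed strain history on a uniform time grid.

    ``time`` must be strictly increasing with constant spacing; the record
    starts from the undeformed state ``(stretch=1, shear=0)``.
    """

    time: np.ndarray  # s
    stretch: np.ndarray  # axial stretch lambda(t), -
    shear: np.ndarray  # amount of shear gamma(t), -

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        lam = np.asarray(self.stretch, dtype=float)
        gam = np.asarray(self.shear, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "stretch", lam)
        object.__setattr__(self, "shear", gam)
        if not (t.shape == lam.shape == gam.shape) or t.ndim != 1 or t.size < 2:
            raise InvalidParameterError("protocol arrays must be equal-length 1-d, n >= 2")
        steps = np.diff(t)
        dt = steps[0]
        if dt <= 0 or np.any(np.abs(steps - dt) > 1e-9 * dt):
            raise InvalidParameterError("protocol time grid must be uniform and increasing")
        if np.any(lam <= 0):
            raise InvalidParameterError("axial stretch must be positive")
        if abs(lam[0] - 1.0) > 1e-12 or abs(gam[0]) > 1e-12:
            raise InvalidParameterError("protocol must start at (stretch=1, shear=0)")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    def __len__(self) -> int:
        return self.time.size


@dataclass(frozen=True)
class StressResponse:
    """Stress channels produced by a protocol: nominal axial ``P`` and shear
    ``tau``, on the protocol's time grid."""

    time: np.ndarray  # s
    P: np.ndarray  # Pa
    tau: np.ndarray  # Pa

    def stack(self) -> np.ndarray:
        """Both channels as an (n, 2) array, column order (P, tau)."""
        return np.column_stack([self.P, self.tau])


def build_deformation_gradient(lambda_ax: float, lambda_lat: float, gamma: float) -> np.ndarray:
    """Deformation gradient of lateral stretch + axial stretch + simple shear.

    Shear acts in the theta-z plane (y-z in the Cartesian stand-in), so
    ``det F = lambda_lat^2 * lambda_ax`` independent of ``gamma``.
    """
    if lambda_ax <= 0 or lambda_lat <= 0:
        raise InvalidParameterError("stretches must be positive")
    return np.array(
        [
            [lambda_lat, 0.0, 0.0],
            [0.0, lambda_lat, gamma * lambda_ax],
            [0.0, 0.0, lambda_ax],
        ]
    )


def _radial_stress(lambda_ax, lambda_lat, gamma, state, dt, params):
    F = build_deformation_gradient(lambda_ax, lambda_lat, gamma)
    sigma, new_state = evaluate_stress(F, state, dt, params)
    return sigma[0, 0], sigma, new_state


def solve_lateral_stretch(
    lambda_ax: float,
    gamma: float,
    state: ViscousState,
    dt: float,
    params: MaterialParameters,
    guess: float = 1.0,
) -> float:
    """Lateral stretch that makes the radial Cauchy stress vanish.

    Safeguarded Newton (secant) iteration starting from ``guess`` (the
    previous step's solution), falling back to bracket expansion plus
    bisection.  Tolerance: ``|sigma_rr| <= 1e-8 (mu_inf + mu_1)``.
    """
    tol = 1e-8 * (params.mu_inf + params.mu_1)

    def res(l):
        return _radial_stress(lambda_ax, l, gamma, state, dt, params)[0]

    # secant from the previous solution
    x0, x1 = guess, guess * (1.0 + 1e-4)
    f0, f1 = res(x0), res(x1)
    for _ in range(30):
        if abs(f1) <= tol:
            return x1
        if f1 == f0:
            break
        x2 = x1 - f1 * (x1 - x0) / (f1 - f0)
        if not np.isfinite(x2) or x2 <= 0.2 * guess or x2 >= 5.0 * guess:
            break
        x0, f0, x1, f1 = x1, f1, x2, res(x2)
    if abs(f1) <= tol:
        return x1

    # bracket expansion + bisection (sigma_rr is increasing in lambda_lat)
    lo, hi = 0.5 * guess, 2.0 * guess
    flo, fhi = res(lo), res(hi)
    for _ in range(20):
        if flo <= 0 <= fhi:
            break
        if flo > 0:
            lo *= 0.7
            flo = res(lo)
        if fhi < 0:
            hi *= 1.4
            fhi = res(hi)
    else:
        raise SimulationError(
            f"could not bracket lateral equilibrium at lambda_ax={lambda_ax}, gamma={gamma}"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        fmid = res(mid)
        if abs(fmid) <= tol:
            return mid
        if fmid < 0:
            lo = mid
        else:
            hi = mid
    raise SimulationError("lateral-stretch bisection did not reach tolerance")


def simulate_response(protocol: LoadingProtocol, params: MaterialParameters) -> StressResponse:
    """Time-step the constitutive law along a protocol.

    Per step: solve the traction-free lateral stretch, commit the viscous
    state, and record ``P = (J sigma F^-T)_zz`` and ``tau = sigma_yz``.  If
    the viscous Newton fails at the protocol step size, the step is halved
    (up to four times) with intermediate strain interpolation.
    """
    n = len(protocol)
    dt = protocol.dt
    P = np.zeros(n)
    tau = np.zeros(n)
    state = ViscousState()
    lam_lat = 1.0

    for i in range(1, n):
        lam_i, gam_i = float(protocol.stretch[i]), float(protocol.shear[i])
        lam_p, gam_p = float(protocol.stretch[i - 1]), float(protocol.shear[i - 1])
        for halvings in range(5):
            nsub = 2**halvings
            try:
                sub_state = state.copy()
                sub_lat = lam_lat
                for k in range(1, nsub + 1):
                    w = k / nsub
                    la = lam_p + w * (lam_i - lam_p)
                    ga = gam_p + w * (gam_i - gam_p)
                    sub_lat = solve_lateral_stretch(
                        la, ga, sub_state, dt / nsub, params, guess=sub_lat
                    )
                    _, sigma, sub_state = _radial_stress(
                        la, sub_lat, ga, sub_state, dt / nsub, params
                    )
                break
            except (IntegrationError, SimulationError):
                if halvings == 4:
                    raise SimulationError(f"integration failed at step {i}")
        state, lam_lat = sub_state, sub_lat
        F = build_deformation_gradient(lam_i, lam_lat, gam_i)
        J = np.linalg.det(F)
        Piola = J * sigma @ np.linalg.inv(F).T
        P[i] = Piola[2, 2]
        tau[i] = sigma[1, 2]

    return StressResponse(time=protocol.time.copy(), P=P, tau=tau)
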