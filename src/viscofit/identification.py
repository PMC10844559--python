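"""Inverse viscoelastic parameter identification.

The misfit between an experimental record and a model prediction is the
normalized L2 error per channel,

    ``chi^2 = sum_i (y_exp_i - y_sim_i)^2 / sum_i y_exp_i^2``,

summed over the nominal-stress and shear-stress channels.  It is minimized
with SciPy's bound-constrained trust-region-reflective least squares on the
stacked per-channel residuals ``(y_exp - y_sim) / sqrt(sum y_exp^2)`` (so
the squared residual norm equals ``chi^2_P + chi^2_tau``), with gradients
by forward finite differences.

The hybrid driver first fits against the cheap LSTM surrogate inside the
training-data parameter box, then restarts from that optimum against the
high-fidelity forward model under the wider physical bounds.  Every model
evaluation — including finite-difference probes and rejected steps — is
logged in the optimization trace.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .active_learning import Box
from .forward_model import LoadingProtocol
from .surrogate import LSTMSurrogate, build_inputs

__all__ = [
    "BoundsTable",
    "OptimizationTrace",
    "chi_squared",
    "residual_vector",
    "fit",
    "hybrid_identify",
    "break_even_fits",
    "DEFAULT_BOUNDS",
]

#: High-fidelity (physical-validity) bounds: alpha in [-100, 100],
#: mu_inf in (0, inf) and eta_1 in (0, 1e5] with zero/infinite entries
#: replaced by tiny-positive / large-finite sentinels, mu_1 in [0, 1e4].
HIGHFID_BOX = Box(
    low=np.array([1e-3, -100.0, 0.0, -100.0, 1e-3]),
    high=np.array([1e8, 100.0, 1e4, 100.0, 1e5]),
)


@dataclass(frozen=True)
class BoundsTable:
    """Optimization bounds per phase: the surrogate phase is restricted to
    the training-data box, the high-fidelity phase to physical validity."""

    surrogate: Box = None  # set in __post_init__ to avoid import cycles
    highfid: Box = field(default_factory=lambda: HIGHFID_BOX)

    def __post_init__(self):
        if self.surrogate is None:
            from .active_learning import DEFAULT_SAMPLING_BOX

            object.__setattr__(self, "surrogate", DEFAULT_SAMPLING_BOX)


DEFAULT_BOUNDS = BoundsTable()


@dataclass
class OptimizationTrace:
    """Log of all model evaluations plus the accepted-iterate subsequence."""

    thetas: list = field(default_factory=list)
    chi2: list = field(default_factory=list)
    phases: list = field(default_factory=list)

    def log(self, theta, chi2, phase):
        self.thetas.append(np.asarray(theta, dtype=float).copy())
        self.chi2.append(float(chi2))
        self.phases.append(phase)

    @property
    def n_evaluations(self) -> int:
        return len(self.chi2)

    def evaluations_in(self, phase: str) -> int:
        return sum(1 for p in self.phases if p == phase)

    def accepted(self, phase: str | None = None):
        """Running-minimum subsequence: (cumulative nfev, theta, chi2)."""
        best = math.inf
        rows = []
        for k, (theta, c, p) in enumerate(zip(self.thetas, self.chi2, self.phases)):
            if phase is not None and p != phase:
                continue
            if c < best:
                best = c
                rows.append((k + 1, theta, c))
        return rows


def chi_squared(y_exp, y_sim) -> float:
    """Normalized L2 error ``sum (y_exp - y_sim)^2 / sum y_exp^2``."""
    y_exp = np.asarray(y_exp, dtype=float).ravel()
    y_sim = np.asarray(y_sim, dtype=float).ravel()
    if y_exp.shape != y_sim.shape:
        raise ValueError("series lengths differ")
    denom = float(np.sum(y_exp**2))
    if denom == 0:
        raise ValueError("experimental channel has zero norm")
    return float(np.sum((y_exp - y_sim) ** 2) / denom)


def residual_vector(record, output) -> np.ndarray:
    """Stacked normalized residuals of both channels.

    ``record`` and ``output`` expose ``P`` and ``tau`` arrays (a rheometer
    record / stress response) or are (n, 2) arrays.  The sum of squares of
    the result equals ``chi2_P + chi2_tau``, making the residuals invariant
    to a uniform rescaling of the experimental stress units.
    """

    def channels(obj):
        if hasattr(obj, "P"):
            return np.asarray(obj.P, float), np.asarray(obj.tau, float)
        arr = np.asarray(obj, dtype=float)
        return arr[:, 0], arr[:, 1]

    parts = []
    for ye, ys in zip(channels(record), channels(output)):
        if ye.shape != ys.shape:
            raise ValueError("experimental and simulated grids differ; resample first")
        norm = float(np.sqrt(np.sum(ye**2)))
        if norm == 0:
            raise ValueError("experimental channel has zero norm")
        parts.append((ye - ys) / norm)
    return np.concatenate(parts)


def fit(
    model_fn,
    record,
    bounds: Box,
    x0: np.ndarray,
    fd_step: float = 1e-6,
    tol: float = 1e-8,
    max_nfev: int | None = None,
    trace: OptimizationTrace | None = None,
    phase: str = "high-fidelity",
):
    """Bounded trust-region-reflective least squares on the stacked residuals.

    ``model_fn`` maps a parameter vector to a stress output on the record's
    grid.  Gradients use forward finite differences with relative step
    ``fd_step``.  Non-finite model outputs are rejected by returning large
    residuals.  Returns ``(best_theta, trace)`` where the trace logs every
    model evaluation (finite-difference probes and failed steps included).
    """
    x0 = np.asarray(x0, dtype=float)
    if np.any(x0 < bounds.low) or np.any(x0 > bounds.high):
        raise ValueError("x0 must lie within the bounds")
    trace = trace if trace is not None else OptimizationTrace()

    def residuals(theta):
        try:
            out = model_fn(theta)
            r = residual_vector(record, out)
        except Exception:  # noqa: BLE001 - reject the point, keep optimizing
            r = None
        if r is None or not np.all(np.isfinite(r)):
            trace.log(theta, np.inf, phase)
            n = len(np.asarray(record.P)) if hasattr(record, "P") else len(record)
            return np.full(2 * n, 1e3)
        trace.log(theta, float(np.sum(r**2)), phase)
        return r

    result = least_squares(
        residuals,
        x0,
        bounds=(bounds.low, bounds.high),
        method="trf",
        jac="2-point",
        diff_step=fd_step,
        x_scale="jac",
        xtol=tol,
        ftol=tol,
        gtol=tol,
        max_nfev=max_nfev,
    )
    return result.x, trace


def hybrid_identify(
    surrogate: LSTMSurrogate,
    highfid_fn,
    record,
    bounds: BoundsTable = DEFAULT_BOUNDS,
    x0: np.ndarray | None = None,
    surrogate_fd_step: float = 1e-3,
    highfid_fd_step: float = 1e-6,
    tol: float = 1e-8,
):
    """Two-phase identification: surrogate first, high-fidelity restart.

    Phase 1 fits the surrogate inside the training-data box (default start:
    box midpoint) until the optimizer's convergence tolerances are met;
    phase 2 restarts the fit from that optimum against ``highfid_fn`` under
    the physical bounds (the phase-1 optimum is clipped into them if
    needed).  Returns ``(theta, trace)`` with phase-tagged evaluations.

    The surrogate's finite-difference step is coarser than the
    high-fidelity one because its float32 outputs limit the attainable
    derivative resolution.
    """
    protocol = LoadingProtocol(
        time=np.asarray(record.time, float),
        stretch=np.asarray(record.stretch, float),
        shear=np.asarray(record.shear, float),
    )

    def surrogate_fn(theta):
        X = build_inputs(theta[None, :], protocol, include_time=surrogate.config.include_time)
        return surrogate.predict(X)[0]

    x0 = bounds.surrogate.midpoint if x0 is None else np.asarray(x0, dtype=float)
    trace = OptimizationTrace()
    theta1, trace = fit(
        surrogate_fn, record, bounds.surrogate, x0,
        fd_step=surrogate_fd_step, tol=tol, trace=trace, phase="surrogate",
    )
    theta1 = np.clip(theta1, bounds.highfid.low, bounds.highfid.high)
    theta2, trace = fit(
        highfid_fn, record, bounds.highfid, theta1,
        fd_step=highfid_fd_step, tol=tol, trace=trace, phase="high-fidelity",
    )
    return theta2, trace


def break_even_fits(n_training_simulations: int, saved_per_fit: int) -> int:
    """Number of fitted experimental curves after which the simulations saved
    by the surrogate amortize the training-set generation cost."""
    if saved_per_fit <= 0:
        raise ValueError("saved_per_fit must be positive")
    return math.ceil(n_training_simulations / saved_per_fit)
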