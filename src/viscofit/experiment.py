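"""Synthetic rheometer experiments.

Generates "experimental" records that emulate a combined rheometer test on a
cylindrical soft-tissue specimen: cyclic compression-tension, compression
and tension stress-relaxation holds, and cyclic torsional shear.  The
rheometer measures axial force ``f_z`` and torque ``t``; geometry-independent
stress measures are ``P = f_z / A`` (nominal axial stress, A the undeformed
cross-section) and ``tau = 2 t / (pi r^3)``.  Raw records are filtered with
a centered moving average followed by Ramer-Douglas-Peucker simplification,
then resampled to a uniform grid — mirroring a typical rheometer
post-processing chain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constitutive import MaterialParameters
from .forward_model import LoadingProtocol, simulate_response

__all__ = [
    "ConfigError",
    "SampleGeometry",
    "RheometerRecord",
    "ProtocolConfig",
    "make_protocol",
    "force_torque_to_stress",
    "stress_to_force_torque",
    "twist_to_shear",
    "moving_average",
    "rdp_simplify",
    "resample_uniform",
    "synth_experiment",
]


class ConfigError(ValueError):
    """Raised for inconsistent protocol or filter configuration."""


@dataclass(frozen=True)
class SampleGeometry:
    """Cylindrical specimen geometry (meters)."""

    radius: float = 4e-3
    height: float = 4e-3

    def __post_init__(self):
        if self.radius <= 0 or self.height <= 0:
            raise ConfigError("geometry dimensions must be positive")

    @property
    def area(self) -> float:
        """Undeformed cross-sectional area ``pi r^2``."""
        return math.pi * self.radius**2


@dataclass
class RheometerRecord:
    """A (possibly filtered) rheometer record on a uniform time grid.

    The force/torque channels and the stress channels are kept consistent:
    ``P = f_z / A`` and ``tau = 2 t / (pi r^3)`` hold exactly.
    """

    time: np.ndarray  # s
    stretch: np.ndarray  # -
    shear: np.ndarray  # -
    f_z: np.ndarray  # N
    torque: np.ndarray  # N m
    P: np.ndarray  # Pa
    tau: np.ndarray  # Pa
    geometry: SampleGeometry = field(default_factory=SampleGeometry)


@dataclass(frozen=True)
class ProtocolConfig:
    """Segment layout of the default test protocol.

    Order: sinusoidal cyclic compression-tension, compression hold, tension
    hold (each hold entered and left by linear ramps), cyclic torsional
    shear at ``lambda = 1``.  All durations must be integer multiples of
    ``dt``.  The default totals 300 samples at ``dt = 0.1 s``.
    """

    dt: float = 0.1  # s
    ct_cycles: int = 2
    ct_amplitude: float = 0.1  # stretch amplitude, lambda in [1-a, 1+a]
    ct_period: float = 6.0  # s
    hold_amplitude: float = 0.1  # stretch offset during the holds
    ramp_time: float = 1.0  # s
    hold_time: float = 4.5  # s
    shear_cycles: int = 2
    shear_amplitude: float = 0.1  # amount of shear
    shear_period: float = 2.45  # s
    waveform: str = "sine"  # "sine" or "triangle" cyclic segments

    def __post_init__(self):
        if self.dt <= 0:
            raise ConfigError("dt must be positive")
        if self.ct_amplitude >= 1 or self.hold_amplitude >= 1:
            raise ConfigError("stretch amplitudes must stay below 1")
        if self.waveform not in ("sine", "triangle"):
            raise ConfigError(f"unknown waveform {self.waveform!r}")


def _n_samples(duration: float, dt: float) -> int:
    n = duration / dt
    if abs(n - round(n)) > 1e-6:
        raise ConfigError(
            f"segment duration {duration} s is not a multiple of dt={dt} s"
        )
    return int(round(n))


def _cycle_wave(n_cycles: int, period: float, dt: float, waveform: str) -> np.ndarray:
    """Unit-amplitude cyclic waveform sampled at dt, excluding t=0."""
    n = _n_samples(n_cycles * period, dt)
    t = dt * np.arange(1, n + 1)
    if waveform == "sine":
        return np.sin(2.0 * math.pi * t / period)
    phase = (t / period) % 1.0
    tri = np.where(phase < 0.25, 4 * phase, np.where(phase < 0.75, 2 - 4 * phase, 4 * phase - 4))
    return tri


def _ramp_hold(target: float, ramp_time: float, hold_time: float, dt: float) -> np.ndarray:
    """0 -> target -> hold -> 0 offset curve, excluding the leading zero."""
    nr = _n_samples(ramp_time, dt)
    nh = _n_samples(hold_time, dt)
    up = target * np.arange(1, nr + 1) / max(nr, 1)
    hold = np.full(nh, target)
    down = target * (1.0 - np.arange(1, nr + 1) / max(nr, 1))
    return np.concatenate([up, hold, down])


def make_protocol(config: ProtocolConfig | None = None) -> LoadingProtocol:
    """Build the segmented loading protocol from its configuration.

    The protocol starts at ``(lambda=1, gamma=0)`` and is continuous across
    segment boundaries.  With all segments empty a two-sample identity
    protocol is returned.
    """
    cfg = config or ProtocolConfig()
    lam_parts = [np.array([1.0])]
    if cfg.ct_cycles > 0:
        lam_parts.append(
            1.0 + cfg.ct_amplitude * _cycle_wave(cfg.ct_cycles, cfg.ct_period, cfg.dt, cfg.waveform)
        )
    if cfg.hold_time > 0 or cfg.ramp_time > 0:
        lam_parts.append(1.0 - _ramp_hold(cfg.hold_amplitude, cfg.ramp_time, cfg.hold_time, cfg.dt))
        lam_parts.append(1.0 + _ramp_hold(cfg.hold_amplitude, cfg.ramp_time, cfg.hold_time, cfg.dt))
    lam = np.concatenate(lam_parts)
    gam = np.zeros_like(lam)
    if cfg.shear_cycles > 0:
        wave = cfg.shear_amplitude * _cycle_wave(cfg.shear_cycles, cfg.shear_period, cfg.dt, cfg.waveform)
        lam = np.concatenate([lam, np.ones_like(wave)])
        gam = np.concatenate([gam, wave])
    if lam.size < 2:  # empty configuration: identity protocol
        lam = np.ones(2)
        gam = np.zeros(2)
    time = cfg.dt * np.arange(lam.size)
    return LoadingProtocol(time=time, stretch=lam, shear=gam)


def force_torque_to_stress(f_z, torque, geom: SampleGeometry):
    """``P = f_z / A`` and ``tau = 2 t / (pi r^3)``."""
    P = np.asarray(f_z, dtype=float) / geom.area
    tau = 2.0 * np.asarray(torque, dtype=float) / (math.pi * geom.radius**3)
    return P, tau


def stress_to_force_torque(P, tau, geom: SampleGeometry):
    """Inverse of :func:`force_torque_to_stress`."""
    f_z = np.asarray(P, dtype=float) * geom.area
    torque = np.asarray(tau, dtype=float) * math.pi * geom.radius**3 / 2.0
    return f_z, torque


def twist_to_shear(phi, geom: SampleGeometry):
    """Amount of shear from twist angle: ``gamma = r phi / h`` at the outer
    radius (the convention matching ``tau = 2 t / (pi r^3)``)."""
    return np.asarray(phi, dtype=float) * geom.radius / geom.height


def moving_average(y, window: int) -> np.ndarray:
    """Centered moving average with shrinking windows at the edges.

    ``window`` must be odd; the output has the input's length.
    """
    if window < 1 or window % 2 == 0:
        raise ConfigError(f"window must be an odd integer >= 1, got {window}")
    y = np.asarray(y, dtype=float)
    if window == 1:
        return y.copy()
    kernel = np.ones(window)
    sums = np.convolve(y, kernel, mode="same")
    counts = np.convolve(np.ones_like(y), kernel, mode="same")
    return sums / counts


def _perp_distance(t, y, i0, i1):
    """Distances of interior points to the chord from i0 to i1."""
    dx, dy = t[i1] - t[i0], y[i1] - y[i0]
    norm = math.hypot(dx, dy)
    tt = t[i0 + 1 : i1] - t[i0]
    yy = y[i0 + 1 : i1] - y[i0]
    if norm == 0.0:
        return np.hypot(tt, yy)
    return np.abs(dx * yy - dy * tt) / norm


def rdp_simplify(t, y, epsilon: float) -> np.ndarray:
    """Ramer-Douglas-Peucker polyline simplification; returns kept indices.

    Endpoints are always kept; a point is dropped only if it lies within
    ``epsilon`` (perpendicular distance) of the local chord.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size != y.size or t.size < 2:
        raise ConfigError("rdp_simplify needs two equal-length arrays, n >= 2")
    if epsilon < 0:
        raise ConfigError("epsilon must be >= 0")
    keep = np.zeros(t.size, dtype=bool)
    keep[0] = keep[-1] = True
    stack = [(0, t.size - 1)]
    while stack:
        i0, i1 = stack.pop()
        if i1 - i0 < 2:
            continue
        d = _perp_distance(t, y, i0, i1)
        k = int(np.argmax(d))
        if d[k] > epsilon:
            mid = i0 + 1 + k
            keep[mid] = True
            stack.append((i0, mid))
            stack.append((mid, i1))
    return np.nonzero(keep)[0]


def resample_uniform(t, y, dt: float):
    """Linear interpolation of ``(t, y)`` onto the uniform grid spanning
    ``[t[0], t[-1]]`` with spacing ``dt``.  No extrapolation."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ConfigError("time must be strictly increasing")
    if dt <= 0:
        raise ConfigError("dt must be positive")
    n = int(math.floor((t[-1] - t[0]) / dt + 1e-9)) + 1
    tu = t[0] + dt * np.arange(n)
    return tu, np.interp(tu, t, y)


def synth_experiment(
    params: MaterialParameters,
    protocol_config: ProtocolConfig | None = None,
    noise_level: float = 0.01,
    geometry: SampleGeometry | None = None,
    seed: int = 0,
    ma_window: int = 5,
    rdp_fraction: float = 0.005,
) -> RheometerRecord:
    """Simulate a noisy, filtered rheometer record.

    Pipeline: simulate the stress response on the configured protocol, add
    independent Gaussian noise per channel (std = ``noise_level`` times the
    channel's peak absolute stress), apply the moving-average filter, thin
    with Ramer-Douglas-Peucker at ``epsilon = rdp_fraction`` times the
    channel peak, and linearly resample back to the protocol's time step.
    Deterministic for a fixed seed.
    """
    cfg = protocol_config or ProtocolConfig()
    geom = geometry or SampleGeometry()
    protocol = make_protocol(cfg)
    resp = simulate_response(protocol, params)
    rng = np.random.default_rng(seed)

    # RDP runs on (sample index, stress / peak) coordinates: with unit-range
    # ordinate and many samples the chords are shallow, so the perpendicular
    # distance is effectively the deviation in stress units and the epsilon
    # fraction refers to the channel peak
    channels = []
    for yclean in (resp.P, resp.tau):
        peak = float(np.max(np.abs(yclean)))
        ynoisy = yclean + rng.normal(0.0, noise_level * peak, size=yclean.shape) if peak > 0 else yclean.copy()
        ysmooth = moving_average(ynoisy, ma_window)
        if peak > 0 and rdp_fraction > 0:
            idx = rdp_simplify(np.arange(resp.time.size, dtype=float), ysmooth / peak, rdp_fraction)
        else:
            idx = np.arange(resp.time.size)
        _, yu = resample_uniform(resp.time[idx], ysmooth[idx], protocol.dt)
        channels.append(yu)
    P, tau = channels
    f_z, torque = stress_to_force_torque(P, tau, geom)
    return RheometerRecord(
        time=protocol.time.copy(),
        stretch=protocol.stretch.copy(),
        shear=protocol.shear.copy(),
        f_z=f_z,
        torque=torque,
        P=P,
        tau=tau,
        geometry=geom,
    )
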