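"""Force-plate mechanics: the driven mass-spring-damper and its transduction.

A force plate is modelled as a single-axis, underdamped harmonic oscillator

    m x'' + c x' + k x = F(t),        c = 2 zeta sqrt(k m)

whose natural frequency f_n = (1/2 pi) sqrt(k/m) is the plate's intrinsic
oscillatory property (IOP).  Any force delivered to the plate excites ringing
at the damped frequency f_n sqrt(1 - zeta^2); the spectral power at that
frequency tracks the total kinetic energy delivered, which is what the IOP
method exploits to measure overall momentum.

The load cell reports the spring force k x, expressed in gram-gravity and
scaled by the cell sensitivity (mV per gram-gravity) and the preamplifier
gain, so a static load of w gram-gravity reads sensitivity * gain * w at the
output.  Integration uses the exact zero-order-hold discretization of the
linear second-order system (state-transition matrix per step), which is
unconditionally stable and exact at the sample instants for piecewise-
constant drive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .errors import InvalidConfigError, InvalidInputError

__all__ = [
    "G0",
    "PlateConfig",
    "ForceTrace",
    "VoltageTrace",
    "natural_frequency",
    "stiffness_for_frequency",
    "simulate_plate",
    "impulse_response",
    "accel_magnitude",
]

#: Standard gravity (m/s^2); 1 gram-gravity = G0 * 1e-3 newton.
G0 = 9.80665


def stiffness_for_frequency(f_target_hz: float, mass_kg: float) -> float:
    """Spring constant k (N/m) giving natural frequency ``f_target_hz`` at ``mass_kg``.

    Inverts f = (1/2 pi) sqrt(k/m):  k = m (2 pi f)^2.
    """
    if f_target_hz <= 0 or mass_kg <= 0:
        raise InvalidConfigError(
            f"frequency and mass must be positive, got f={f_target_hz}, m={mass_kg}"
        )
    return mass_kg * (2.0 * math.pi * f_target_hz) ** 2


@dataclass(frozen=True)
class PlateConfig:
    """Physical and transduction constants of one (simulated) force plate.

    Parameters
    ----------
    mass_kg : total oscillating mass, plate plus payload (kg).
    stiffness_N_per_m : spring constant k (N/m).
    damping_ratio : dimensionless zeta in (0, 1); the plate must be
        underdamped so taps produce ring-down at the IOP frequency.
    sensitivity_mV_per_g : load-cell output per gram-gravity of spring force.
    gain : preamplifier multiplier (dimensionless, >= 1).
    fs_hz : output sampling rate (Hz).
    """

    mass_kg: float = 0.5
    stiffness_N_per_m: float = field(
        default_factory=lambda: stiffness_for_frequency(42.0, 0.5)
    )
    damping_ratio: float = 0.05
    sensitivity_mV_per_g: float = 33.0
    gain: float = 1000.0
    fs_hz: float = 1000.0

    def __post_init__(self) -> None:
        if self.mass_kg <= 0 or self.stiffness_N_per_m <= 0:
            raise InvalidConfigError(
                f"mass and stiffness must be positive, got m={self.mass_kg}, "
                f"k={self.stiffness_N_per_m}"
            )
        if not 0.0 < self.damping_ratio < 1.0:
            raise InvalidConfigError(
                f"damping_ratio must lie in (0, 1), got {self.damping_ratio}"
            )
        if self.sensitivity_mV_per_g <= 0:
            raise InvalidConfigError("sensitivity_mV_per_g must be positive")
        if self.gain < 1:
            raise InvalidConfigError("gain must be >= 1")
        if self.fs_hz <= 0:
            raise InvalidConfigError("fs_hz must be positive")
        if natural_frequency(self) >= self.fs_hz / 2:
            raise InvalidConfigError(
                f"natural frequency {natural_frequency(self):.1f} Hz is not "
                f"below Nyquist ({self.fs_hz / 2:.1f} Hz)"
            )


def natural_frequency(config: PlateConfig) -> float:
    """Undamped natural frequency f_n = (1/2 pi) sqrt(k/m), in Hz."""
    if config.mass_kg <= 0 or config.stiffness_N_per_m <= 0:
        raise InvalidConfigError("mass and stiffness must be positive")
    return math.sqrt(config.stiffness_N_per_m / config.mass_kg) / (2.0 * math.pi)


@dataclass
class ForceTrace:
    """Uniformly sampled external-force drive (newton, signed)."""

    values: np.ndarray
    fs_hz: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise InvalidInputError("force trace must be one-dimensional")
        if self.fs_hz <= 0:
            raise InvalidInputError("fs_hz must be positive")

    @property
    def duration_s(self) -> float:
        return len(self.values) / self.fs_hz

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.fs_hz


@dataclass
class VoltageTrace:
    """Preamplified load-cell output (mV), nominally sampled at 1000 Hz."""

    values: np.ndarray
    fs_hz: float = 1000.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise InvalidInputError("voltage trace must be one-dimensional")
        if self.fs_hz <= 0:
            raise InvalidInputError("fs_hz must be positive")

    @property
    def duration_s(self) -> float:
        return len(self.values) / self.fs_hz

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.fs_hz


def _system_matrices(m: float, k: float, c: float):
    """Continuous state-space (x, x') with spring-force output k*x (N)."""
    a = np.array([[0.0, 1.0], [-k / m, -c / m]])
    b = np.array([[0.0], [1.0 / m]])
    cmat = np.array([[k, 0.0]])
    d = np.array([[0.0]])
    return a, b, cmat, d


def simulate_plate(
    config: PlateConfig,
    drive: ForceTrace,
    payload_g: float = 0.0,
    seed: int | None = None,
    noise_sd_mv: float = 0.0,
    remove_baseline: bool = True,
) -> VoltageTrace:
    """Simulate the plate response to an external force drive.

    The payload mass (gram) is added to the oscillating mass and its weight
    enters as a constant force, so at static equilibrium the (un-baselined)
    output reads sensitivity * gain * payload_g.  ``remove_baseline``
    subtracts that known static offset — the analysis pipelines care about
    dynamics only and a DC term would dominate the PSD.

    The response is linear: ``simulate_plate(alpha * F) == alpha *
    simulate_plate(F)`` after baseline removal and with noise disabled.

    Parameters
    ----------
    drive : external force (N).  ``drive.fs_hz`` must be an integer multiple
        of ``config.fs_hz``; the integration runs at the drive rate (exact
        for piecewise-constant force) and is anti-alias decimated when the
        rates differ.
    noise_sd_mv : additive Gaussian sensor noise (mV) at the output rate,
        drawn from ``seed``.
    """
    if not np.all(np.isfinite(drive.values)):
        raise InvalidInputError("drive contains NaN or infinite samples")
    if payload_g < 0:
        raise InvalidInputError("payload_g must be non-negative")
    if drive.fs_hz < config.fs_hz:
        raise InvalidInputError(
            f"drive rate {drive.fs_hz} Hz below output rate {config.fs_hz} Hz; "
            "resample the drive first"
        )
    ratio = drive.fs_hz / config.fs_hz
    if abs(ratio - round(ratio)) > 1e-9:
        raise InvalidInputError(
            f"drive rate {drive.fs_hz} must be an integer multiple of "
            f"output rate {config.fs_hz}"
        )
    ratio = int(round(ratio))

    m = config.mass_kg + payload_g * 1e-3
    k = config.stiffness_N_per_m
    c = 2.0 * config.damping_ratio * math.sqrt(k * m)

    force = drive.values + payload_g * 1e-3 * G0
    dt = 1.0 / drive.fs_hz
    ad, bd, cd, dd, _ = signal.cont2discrete(_system_matrices(m, k, c), dt, method="zoh")
    _, y, _ = signal.dlsim((ad, bd, cd, dd, dt), force)
    spring_force_n = y[:, 0]

    if ratio > 1:
        spring_force_n = signal.decimate(spring_force_n, ratio, ftype="fir", zero_phase=True)

    spring_g = spring_force_n / (G0 * 1e-3)  # gram-gravity
    volts = config.gain * config.sensitivity_mV_per_g * spring_g
    if remove_baseline:
        volts = volts - config.gain * config.sensitivity_mV_per_g * payload_g
    if noise_sd_mv > 0:
        rng = np.random.default_rng(seed)
        volts = volts + rng.normal(0.0, noise_sd_mv, size=volts.shape)
    return VoltageTrace(values=volts, fs_hz=config.fs_hz)


def impulse_response(
    config: PlateConfig,
    duration_s: float,
    payload_g: float = 0.0,
    output: str = "displacement",
) -> np.ndarray:
    """Response to a unit Dirac impulse (1 N s) at t = 0, sampled at config.fs_hz.

    Propagates the post-impulse state (x = 0, x' = 1/m) with the same exact
    state-transition matrix used by :func:`simulate_plate`.  The closed form
    is x(t) = (1/(m w_d)) e^(-zeta w_n t) sin(w_d t) with
    w_d = w_n sqrt(1 - zeta^2).

    ``output`` is ``"displacement"`` (m) or ``"voltage"`` (mV, baseline-free).
    """
    if output not in ("displacement", "voltage"):
        raise InvalidInputError(f"unknown output kind {output!r}")
    m = config.mass_kg + payload_g * 1e-3
    k = config.stiffness_N_per_m
    c = 2.0 * config.damping_ratio * math.sqrt(k * m)
    dt = 1.0 / config.fs_hz
    ad, *_ = signal.cont2discrete(_system_matrices(m, k, c), dt, method="zoh")

    n = int(round(duration_s * config.fs_hz))
    states = np.empty((n, 2))
    state = np.array([0.0, 1.0 / m])
    for i in range(n):
        states[i] = state
        state = ad @ state
    x = states[:, 0]
    if output == "displacement":
        return x
    spring_g = k * x / (G0 * 1e-3)
    return config.gain * config.sensitivity_mV_per_g * spring_g


def accel_magnitude(accel) -> np.ndarray:
    """Per-sample Euclidean norm of a 3-axis acceleration recording (g).

    Accepts any object with equal-length ``x``, ``y``, ``z`` arrays.
    """
    x = np.asarray(accel.x, dtype=float)
    y = np.asarray(accel.y, dtype=float)
    z = np.asarray(accel.z, dtype=float)
    if not (len(x) == len(y) == len(z)):
        raise InvalidInputError(
            f"component lengths differ: {len(x)}, {len(y)}, {len(z)}"
        )
    return np.sqrt(x * x + y * y + z * z)
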