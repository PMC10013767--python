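"""Seeded synthetic drives and parallel accelerometer / video channels.

Each generator emulates one recording condition used to exercise the IOP
pipelines:

* random / periodic mechanical tapping (plate validation),
* a freely moving mouse, wild-type or Grid2-like with a 20 Hz action tremor
  whose force amplitude scales with the locomotor envelope,
* rectified optogenetic pulse-train forcing at 16 or 20 Hz,
* nonrhythmic natural movement with an epoch-varying intensity envelope.

All randomness flows through ``numpy.random.default_rng(seed)``, so identical
``ScenarioParams`` produce bit-identical outputs.  The locomotor envelope is
a mean-reverting (Ornstein-Uhlenbeck-style) process with ~2 s correlation
time, clipped at zero: slow, non-negative, stationary variation of activity.
Taps are half-sine force pulses ~5 ms wide — broadband below ~100 Hz, like
mechanical tapping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

from .errors import InvalidConfigError, InvalidInputError
from .mechanics import ForceTrace

__all__ = [
    "ScenarioParams",
    "AccelTrace",
    "TrackTrace",
    "gen_random_tapping",
    "gen_periodic_tapping",
    "gen_mouse_motion",
    "gen_optogenetic",
    "gen_natural_movement",
    "locomotor_envelope",
    "exp_background_noise",
]

_KINDS = (
    "random_tapping",
    "periodic_tapping",
    "wt_mouse",
    "grid2_mouse",
    "optogenetic",
    "natural_movement",
)


@dataclass(frozen=True)
class ScenarioParams:
    """Parameters of one synthetic recording scenario.

    Only the fields relevant to ``kind`` are consulted; the rest keep their
    defaults.  Amplitudes are newtons of peak tap force; ``locomotor_level``
    scales the activity envelope; ``tremor_coupling`` is tremor force (N) per
    unit envelope and must be zero for wild-type scenarios.
    """

    kind: str
    duration_s: float = 60.0
    seed: int = 0
    fs_hz: float = 1000.0
    # tapping
    tap_rate_hz: float = 3.0
    tap_freq_hz: float = 5.0
    tap_amp_N: float = 0.5
    impulse_width_s: float = 0.005
    # mouse motion
    locomotor_level: float = 1.0
    envelope_tau_s: float = 2.0
    tremor_freq_hz: float = 20.0
    tremor_coupling: float = 0.0
    # optogenetics: (start_s, stop_s) light-on intervals
    opto_freq_hz: float = 20.0
    opto_power: float = 1.0
    opto_blocks: tuple = ()
    # natural movement epochs
    n_epochs: int = 1
    epoch_s: float = 2.0
    envelope_range: float = 1.0
    # sensors
    noise_sd: float = 0.0
    pixel_mm: float = 0.22
    fps: float = 60.0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise InvalidConfigError(
                f"unknown scenario kind {self.kind!r}; expected one of {_KINDS}"
            )
        if self.duration_s <= 0:
            raise InvalidConfigError("duration_s must be positive")
        for name in ("tap_rate_hz", "tap_freq_hz", "tap_amp_N", "locomotor_level",
                     "opto_power", "noise_sd", "envelope_range"):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be non-negative")
        if self.tremor_coupling < 0:
            raise InvalidConfigError("tremor_coupling must be non-negative")
        if self.kind == "wt_mouse" and self.tremor_coupling != 0:
            raise InvalidConfigError("tremor_coupling must be 0 for wt_mouse")
        if self.fs_hz <= 0 or self.fps <= 0:
            raise InvalidConfigError("sampling rates must be positive")


@dataclass
class AccelTrace:
    """3-axis head-mounted accelerometer recording (g) at 1000 Hz."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    fs_hz: float = 1000.0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if not (len(self.x) == len(self.y) == len(self.z)):
            raise InvalidInputError("accelerometer components must have equal length")


#: Open-field arena size (mm), matching a 28 cm x 16 cm field.
ARENA_MM = (280.0, 160.0)


@dataclass
class TrackTrace:
    """Video body-center coordinates (mm) at 60 frames/s, pixel-quantized."""

    x_mm: np.ndarray
    y_mm: np.ndarray
    fps: float = 60.0
    pixel_mm: float = 0.22

    def __post_init__(self) -> None:
        self.x_mm = np.asarray(self.x_mm, dtype=float)
        self.y_mm = np.asarray(self.y_mm, dtype=float)
        if len(self.x_mm) != len(self.y_mm):
            raise InvalidInputError("track coordinates must have equal length")


# ---------------------------------------------------------------------------
# building blocks


def _add_half_sine(values: np.ndarray, fs: float, t_events, amps, width_s: float):
    """Superpose half-sine pulses of the given peak amplitudes in place."""
    n = len(values)
    wsamp = max(2, int(round(width_s * fs)))
    pulse = np.sin(np.pi * np.arange(wsamp) / (wsamp - 1))
    for t0, a in zip(np.atleast_1d(t_events), np.atleast_1d(amps)):
        i0 = int(round(t0 * fs))
        if i0 >= n:
            continue
        i1 = min(n, i0 + wsamp)
        values[i0:i1] += a * pulse[: i1 - i0]


def locomotor_envelope(
    rng: np.random.Generator,
    n: int,
    fs: float,
    tau_s: float = 2.0,
    mean: float = 1.0,
    sd: float = 0.5,
) -> np.ndarray:
    """Non-negative, slowly varying activity envelope L(t).

    Mean-reverting Gaussian process with correlation time ``tau_s``,
    stationary mean ``mean`` and standard deviation ``sd``, clipped at zero.
    """
    dt = 1.0 / fs
    a = math.exp(-dt / tau_s)
    noise_sd = sd * math.sqrt(1.0 - a * a)
    eps = rng.normal(0.0, noise_sd, size=n)
    eps[0] = rng.normal(0.0, sd)
    x = _signal.lfilter([1.0], [1.0, -a], eps)  # AR(1) recursion, vectorized
    return np.clip(mean + x, 0.0, None)


def exp_background_noise(
    rng: np.random.Generator,
    n: int,
    fs: float,
    decay_per_hz: float = 0.05,
    amplitude: float = 1.0,
) -> np.ndarray:
    """Gaussian noise whose PSD decays exponentially with frequency.

    White noise is shaped in the frequency domain with amplitude
    exp(-decay_per_hz * f / 2), so the power spectrum falls as
    exp(-decay_per_hz * f): the broadband background that head-mounted
    accelerometers show.
    """
    white = rng.normal(0.0, 1.0, size=n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    spec *= np.exp(-decay_per_hz * f / 2.0)
    shaped = np.fft.irfft(spec, n=n)
    rms = np.sqrt(np.mean(shaped**2))
    return amplitude * shaped / max(rms, 1e-30)


# ---------------------------------------------------------------------------
# generators


def gen_random_tapping(params: ScenarioParams) -> ForceTrace:
    """Poisson-timed half-sine taps with gamma-distributed peak force.

    Event times are homogeneous Poisson at ``tap_rate_hz``; peak amplitudes
    are Gamma(shape 4, mean ``tap_amp_N``) — positive, right-skewed, like
    manual tapping of varying strength.  Zero rate yields a zero trace.
    """
    if params.kind != "random_tapping":
        raise InvalidConfigError(f"expected kind random_tapping, got {params.kind}")
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration_s * params.fs_hz))
    values = np.zeros(n)
    if params.tap_rate_hz > 0:
        n_events = rng.poisson(params.tap_rate_hz * params.duration_s)
        times = np.sort(rng.uniform(0.0, params.duration_s, size=n_events))
        amps = rng.gamma(4.0, params.tap_amp_N / 4.0, size=n_events)
        _add_half_sine(values, params.fs_hz, times, amps, params.impulse_width_s)
    return ForceTrace(values=values, fs_hz=params.fs_hz)


def gen_periodic_tapping(params: ScenarioParams) -> ForceTrace:
    """Strictly periodic tap train at ``tap_freq_hz`` (metronome tapping)."""
    if params.tap_freq_hz <= 0:
        raise InvalidConfigError("tap_freq_hz must be positive")
    if params.tap_freq_hz >= params.fs_hz / 2:
        raise InvalidConfigError(
            f"tap_freq_hz {params.tap_freq_hz} at or above Nyquist "
            f"({params.fs_hz / 2} Hz) would alias"
        )
    n = int(round(params.duration_s * params.fs_hz))
    values = np.zeros(n)
    n_taps = int(math.floor(params.duration_s * params.tap_freq_hz))
    times = np.arange(n_taps) / params.tap_freq_hz
    amps = np.full(n_taps, params.tap_amp_N)
    _add_half_sine(values, params.fs_hz, times, amps, params.impulse_width_s)
    return ForceTrace(values=values, fs_hz=params.fs_hz)


def _mouse_force(params: ScenarioParams, rng: np.random.Generator,
                 envelope: np.ndarray) -> np.ndarray:
    """Locomotor impulse drive + (optionally) envelope-coupled tremor force."""
    n = len(envelope)
    fs = params.fs_hz
    t = np.arange(n) / fs
    values = np.zeros(n)

    # Poisson impulses whose strength scales with L(t); the rate stays fixed
    # so locomotor band power scales as L^2, matching the tremor term — the
    # linear amplitude coupling the tremor model requires
    base_rate = 20.0  # events/s: ~5 footfalls/s across four paws
    p_event = np.full(n, min(base_rate / fs, 1.0))
    events = rng.random(n) < p_event
    idx = np.nonzero(events)[0]
    amps = params.tap_amp_N * envelope[idx] * rng.gamma(9.0, 1.0 / 9.0, size=len(idx))
    _add_half_sine(values, fs, idx / fs, amps, params.impulse_width_s)

    coupling = params.tremor_coupling if params.kind == "grid2_mouse" else 0.0
    if coupling > 0:
        # sustained oscillation, phase continuous across the record
        values += coupling * envelope * np.sin(2.0 * math.pi * params.tremor_freq_hz * t)
    return values


def _mouse_accel(params: ScenarioParams, rng: np.random.Generator,
                 force: np.ndarray, envelope: np.ndarray) -> AccelTrace:
    n = len(force)
    fs = params.fs_hz
    t = np.arange(n) / fs
    # head acceleration ~ plate-local force scaled to g, unevenly split by axis
    base = force / (0.03 * 9.81)  # 30 g head assembly
    tremor = np.sin(2.0 * math.pi * params.tremor_freq_hz * t) * envelope
    coupling = params.tremor_coupling if params.kind == "grid2_mouse" else 0.0
    axes = []
    for share, tshare in ((0.6, 0.7), (0.3, 0.2), (0.1, 0.1)):
        bg = exp_background_noise(rng, n, fs, decay_per_hz=0.05,
                                  amplitude=0.05 + params.noise_sd)
        axes.append(share * 0.02 * base + coupling * tshare * 0.05 * tremor + bg)
    return AccelTrace(x=axes[0], y=axes[1], z=axes[2], fs_hz=fs)


def _mouse_track(params: ScenarioParams, rng: np.random.Generator,
                 envelope: np.ndarray) -> TrackTrace:
    n_frames = int(round(params.duration_s * params.fps))
    step = max(1, int(round(params.fs_hz / params.fps)))
    env_f = envelope[::step][:n_frames]
    if len(env_f) < n_frames:
        env_f = np.pad(env_f, (0, n_frames - len(env_f)), mode="edge")
    # heading random walk; speed proportional to the envelope
    dtheta = rng.normal(0.0, 0.4, size=n_frames)
    theta = np.cumsum(dtheta)
    speed = 60.0 * env_f / params.fps  # mm per frame at unit envelope: 1 mm
    x = np.empty(n_frames)
    y = np.empty(n_frames)
    x[0], y[0] = ARENA_MM[0] / 2, ARENA_MM[1] / 2
    for i in range(1, n_frames):
        x[i] = x[i - 1] + speed[i] * math.cos(theta[i])
        y[i] = y[i - 1] + speed[i] * math.sin(theta[i])
        # reflect at arena walls
        if not 0 <= x[i] <= ARENA_MM[0]:
            x[i] = np.clip(x[i], 0, ARENA_MM[0]) * 2 - x[i]
            theta[i:] = math.pi - theta[i:]
        if not 0 <= y[i] <= ARENA_MM[1]:
            y[i] = np.clip(y[i], 0, ARENA_MM[1]) * 2 - y[i]
            theta[i:] = -theta[i:]
    # marker-estimation noise: 0.5 px Gaussian jitter, then pixel quantization
    jitter = 0.5 * params.pixel_mm
    x = x + rng.normal(0.0, jitter, size=n_frames)
    y = y + rng.normal(0.0, jitter, size=n_frames)
    x = np.round(x / params.pixel_mm) * params.pixel_mm
    y = np.round(y / params.pixel_mm) * params.pixel_mm
    x = np.clip(x, 0, ARENA_MM[0])
    y = np.clip(y, 0, ARENA_MM[1])
    return TrackTrace(x_mm=x, y_mm=y, fps=params.fps, pixel_mm=params.pixel_mm)


#: Default Grid2 tremor coupling (N of 20 Hz force per unit envelope) — puts
#: the tremor band on the same order as the IOP band, the regime in which a
#: clear tremor peak rides on the locomotor spectrum.
GRID2_COUPLING = 1.2


def gen_mouse_motion(
    params: ScenarioParams,
    envelope: np.ndarray | None = None,
) -> tuple[ForceTrace, AccelTrace, TrackTrace]:
    """Freely moving mouse: force drive + accelerometer + video track.

    A slowly varying locomotor envelope L(t) modulates both the rate and the
    strength of broadband impulses; for ``grid2_mouse`` a sustained tremor
    force ``tremor_coupling * L(t) * sin(2 pi f_tremor t)`` is added, so
    tremor amplitude scales linearly with locomotor intensity.  All three
    channels share one clock and one envelope.

    ``envelope`` overrides the generated L(t) (same length as the force
    trace), e.g. to impose per-epoch activity levels.
    """
    if params.kind not in ("wt_mouse", "grid2_mouse"):
        raise InvalidConfigError(f"expected a mouse kind, got {params.kind!r}")
    p = params
    rng = np.random.default_rng(p.seed)
    n = int(round(p.duration_s * p.fs_hz))
    if envelope is None:
        env = p.locomotor_level * locomotor_envelope(rng, n, p.fs_hz, p.envelope_tau_s)
    else:
        env = np.asarray(envelope, dtype=float)
        if len(env) != n:
            raise InvalidInputError(
                f"envelope length {len(env)} != expected {n} samples"
            )
        if np.any(env < 0):
            raise InvalidInputError("envelope must be non-negative")
    force = _mouse_force(p, rng, env)
    accel = _mouse_accel(p, rng, force, env)
    track = _mouse_track(p, rng, env)
    return ForceTrace(values=force, fs_hz=p.fs_hz), accel, track


def grid2_params(**overrides) -> ScenarioParams:
    """Convenience constructor for the Grid2 tremor scenario at default coupling."""
    kw = dict(kind="grid2_mouse", tremor_coupling=GRID2_COUPLING)
    kw.update(overrides)
    return ScenarioParams(**kw)


def gen_optogenetic(params: ScenarioParams) -> ForceTrace:
    """Rectified pulse-train forcing during light-on blocks.

    During each (start_s, stop_s) on-interval, non-negative half-sine force
    pulses repeat at ``opto_freq_hz``, each spanning half a drive period
    (a half-wave-rectified sinusoid: the limb pushes during half of every
    cycle, never pulls), with peak amplitude proportional to ``opto_power``;
    a low-level natural-movement background runs throughout.  Rectification
    guarantees harmonic content at 2x the drive frequency while the
    fundamental stays dominant.
    """
    if params.kind != "optogenetic":
        raise InvalidConfigError(f"expected kind optogenetic, got {params.kind}")
    if not params.opto_blocks:
        raise InvalidConfigError("opto_blocks must be non-empty")
    blocks = sorted(tuple(b) for b in params.opto_blocks)
    prev_stop = -math.inf
    for start, stop in blocks:
        if stop <= start:
            raise InvalidConfigError(f"block ({start}, {stop}) has stop <= start")
        if start < prev_stop:
            raise InvalidConfigError("opto_blocks overlap")
        prev_stop = stop

    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration_s * params.fs_hz))
    values = np.zeros(n)
    # faint background movement at all times
    n_bg = rng.poisson(1.0 * params.duration_s)
    bg_times = np.sort(rng.uniform(0.0, params.duration_s, size=n_bg))
    bg_amps = rng.gamma(4.0, 0.05 * params.tap_amp_N / 4.0, size=n_bg)
    _add_half_sine(values, params.fs_hz, bg_times, bg_amps, params.impulse_width_s)

    amp = params.opto_power * params.tap_amp_N  # linear power -> force map (synthetic)
    if amp > 0:
        period = 1.0 / params.opto_freq_hz
        for start, stop in blocks:
            times = np.arange(start, min(stop, params.duration_s), period)
            amps = amp * (1.0 + 0.05 * rng.standard_normal(len(times)))
            _add_half_sine(values, params.fs_hz, times, np.abs(amps),
                           0.5 * period)
    return ForceTrace(values=values, fs_hz=params.fs_hz)


def gen_natural_movement(params: ScenarioParams) -> ForceTrace:
    """Nonrhythmic broadband drive with an epoch-wise intensity envelope.

    The record is ``n_epochs`` epochs of ``epoch_s`` seconds.  Epoch
    intensity levels span ``envelope_range``-fold (geometrically spaced,
    shuffled), scaling impulse amplitude; there is no periodic component
    anywhere in 2-30 Hz.  ``locomotor_level`` scales everything; zero level
    gives a zero trace.
    """
    if params.kind != "natural_movement":
        raise InvalidConfigError(f"expected kind natural_movement, got {params.kind}")
    rng = np.random.default_rng(params.seed)
    n_ep = params.n_epochs
    fs = params.fs_hz
    n_per = int(round(params.epoch_s * fs))
    n = n_ep * n_per
    levels = np.geomspace(1.0, max(params.envelope_range, 1.0), n_ep)
    rng.shuffle(levels)
    env = np.repeat(levels, n_per) * params.locomotor_level

    values = np.zeros(n)
    base_rate = 20.0  # events/s
    p_event = np.clip(base_rate / fs * np.ones(n), 0.0, 1.0)
    events = rng.random(n) < p_event
    idx = np.nonzero(events)[0]
    amps = params.tap_amp_N * env[idx] * rng.gamma(9.0, 1.0 / 9.0, size=len(idx))
    _add_half_sine(values, fs, idx / fs, amps, params.impulse_width_s)
    if params.locomotor_level == 0:
        values[:] = 0.0
    return ForceTrace(values=values, fs_hz=fs)
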