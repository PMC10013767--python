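"""PSD estimation, band power, peak determination, and video velocity.

The estimator is Welch's averaged modified periodogram (Hann window, 1 s
segments giving 1 Hz resolution, 50% overlap) — enough to separate the
16/20 Hz rhythmic drives from the ~42 Hz plate resonance.  Peak
determination follows the concave-downward rule: a candidate bin must be a
strict local maximum with negative centred second difference inside the
search window; the highest candidate wins, ties break toward lower
frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .errors import (
    InsufficientDataError,
    InvalidBandError,
    InvalidInputError,
    InvalidWindowError,
)

__all__ = [
    "Spectrum",
    "Spectrogram",
    "PeakResult",
    "VelocitySeries",
    "welch_psd",
    "spectrogram",
    "band_power",
    "find_peak",
    "velocity_from_track",
    "pixel_resolution",
]


@dataclass
class Spectrum:
    """One-sided PSD on a uniform frequency grid (signal-units^2 / Hz)."""

    freqs: np.ndarray
    psd: np.ndarray
    df: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.psd = np.asarray(self.psd, dtype=float)
        if self.freqs.shape != self.psd.shape:
            raise InvalidInputError("freqs and psd must have the same shape")
        if len(self.freqs) >= 2:
            steps = np.diff(self.freqs)
            if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-6):
                raise InvalidInputError("frequency grid must be uniform and increasing")
        if np.any(self.psd < 0):
            raise InvalidInputError("psd must be non-negative")


@dataclass
class Spectrogram:
    """Per-epoch spectra sharing one frequency grid; rows are epochs."""

    epoch_times: np.ndarray  # (n_epochs, 2) start/stop seconds
    freqs: np.ndarray
    rows: np.ndarray  # (n_epochs, n_freqs)
    df: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.epoch_times = np.asarray(self.epoch_times, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.rows = np.asarray(self.rows, dtype=float)
        if self.rows.shape != (len(self.epoch_times), len(self.freqs)):
            raise InvalidInputError("rows shape must be (n_epochs, n_freqs)")
        starts, stops = self.epoch_times[:, 0], self.epoch_times[:, 1]
        if np.any(stops <= starts) or np.any(starts[1:] < stops[:-1]):
            raise InvalidInputError("epochs must be ordered and non-overlapping")

    @property
    def n_epochs(self) -> int:
        return len(self.epoch_times)

    def epoch(self, i: int) -> Spectrum:
        return Spectrum(self.freqs, self.rows[i], self.df, dict(self.meta))

    def mean_spectrum(self) -> Spectrum:
        return Spectrum(self.freqs, self.rows.mean(axis=0), self.df, dict(self.meta))


@dataclass
class PeakResult:
    """Outcome of concave-peak search: frequency, height, and whether found."""

    freq: float
    height: float
    found: bool


@dataclass
class VelocitySeries:
    """Frame-by-frame body-center speed (mm/s); length = frames - 1."""

    values: np.ndarray
    fps: float = 60.0
    pixel_mm: float = 0.22

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise InvalidInputError("speeds must be non-negative")

    @property
    def fs_hz(self) -> float:
        return self.fps


def _values_fs(trace) -> tuple[np.ndarray, float]:
    if isinstance(trace, np.ndarray):
        raise InvalidInputError("pass a trace object with values and fs_hz")
    return np.asarray(trace.values, dtype=float), float(trace.fs_hz)


def welch_psd(trace, window_s: float = 1.0, overlap_frac: float = 0.5) -> Spectrum:
    """Welch PSD of a trace (any object with ``values`` and ``fs_hz``).

    Hann window, constant detrend, ``window_s``-second segments at
    ``overlap_frac`` overlap.  Satisfies Parseval to within window effects:
    the integral of the PSD approximates the trace variance.
    """
    x, fs = _values_fs(trace)
    if not 0 <= overlap_frac < 1:
        raise InvalidInputError("overlap_frac must be in [0, 1)")
    nperseg = int(round(window_s * fs))
    if nperseg < 2:
        raise InvalidInputError("window_s too short for this sampling rate")
    if len(x) < nperseg:
        raise InsufficientDataError(
            f"trace has {len(x)} samples, needs at least {nperseg} (one window)"
        )
    freqs, psd = signal.welch(
        x,
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=int(round(overlap_frac * nperseg)),
        detrend="constant",
        scaling="density",
    )
    df = freqs[1] - freqs[0]
    n_seg = 1 + (len(x) - nperseg) // max(1, nperseg - int(round(overlap_frac * nperseg)))
    meta = {"window_s": window_s, "overlap_frac": overlap_frac, "n_segments": n_seg,
            "fs_hz": fs}
    return Spectrum(freqs=freqs, psd=psd, df=df, meta=meta)


def spectrogram(trace, epoch_s: float = 2.0, window_s: float = 1.0,
                overlap_frac: float = 0.5) -> Spectrogram:
    """Split a trace into consecutive epochs and Welch-estimate each.

    ``epoch_s`` must be >= 1 s (>= 1 Hz resolution, needed to separate the
    16/20/~42 Hz features).  Averaging the rows approximates the whole-record
    PSD.
    """
    x, fs = _values_fs(trace)
    if epoch_s < 1.0:
        raise InvalidInputError("epoch_s must be >= 1 s")
    n_per = int(round(epoch_s * fs))
    n_epochs = len(x) // n_per
    if n_epochs < 1:
        raise InsufficientDataError(
            f"record of {len(x) / fs:.2f} s shorter than one {epoch_s} s epoch"
        )
    rows = []
    times = []
    for i in range(n_epochs):
        seg = x[i * n_per:(i + 1) * n_per]
        spec = welch_psd(_Seg(seg, fs), window_s, overlap_frac)
        rows.append(spec.psd)
        times.append((i * epoch_s, (i + 1) * epoch_s))
    return Spectrogram(
        epoch_times=np.array(times),
        freqs=spec.freqs,
        rows=np.array(rows),
        df=spec.df,
        meta={"epoch_s": epoch_s, "window_s": window_s, "overlap_frac": overlap_frac,
              "fs_hz": fs},
    )


@dataclass
class _Seg:
    values: np.ndarray
    fs_hz: float


def _grid_of(spectrum) -> tuple[np.ndarray, np.ndarray, float]:
    """Frequency grid and values of a Spectrum or NormalizedSpectrum."""
    freqs = np.asarray(spectrum.freqs, dtype=float)
    vals = getattr(spectrum, "psd", None)
    if vals is None:
        vals = spectrum.values
    vals = np.asarray(vals, dtype=float)
    df = getattr(spectrum, "df", None) or (freqs[1] - freqs[0])
    return freqs, vals, float(df)


def band_power(spectrum, band_lo: float, band_hi: float) -> float:
    """Integrated power over the closed band [band_lo, band_hi] (sum * df)."""
    freqs, vals, df = _grid_of(spectrum)
    if band_hi < band_lo:
        raise InvalidBandError(f"empty band ({band_lo}, {band_hi})")
    if band_lo < freqs[0] - 1e-9 or band_hi > freqs[-1] + 1e-9:
        raise InvalidBandError(
            f"band ({band_lo}, {band_hi}) outside grid "
            f"[{freqs[0]}, {freqs[-1]}]"
        )
    mask = (freqs >= band_lo - 1e-9) & (freqs <= band_hi + 1e-9)
    return float(vals[mask].sum() * df)


def find_peak(spectrum, window_lo: float, window_hi: float) -> PeakResult:
    """Concave-downward peak search inside [window_lo, window_hi].

    Candidates are interior window bins that are strict local maxima with
    negative centred second difference; the highest candidate is returned,
    ties broken toward lower frequency.  ``found=False`` when the window
    holds no local maximum (e.g. monotone spectra).
    """
    freqs, vals, _ = _grid_of(spectrum)
    if window_lo < freqs[0] - 1e-9 or window_hi > freqs[-1] + 1e-9:
        raise InvalidWindowError(
            f"window ({window_lo}, {window_hi}) outside grid"
        )
    idx = np.nonzero((freqs >= window_lo - 1e-9) & (freqs <= window_hi + 1e-9))[0]
    if len(idx) < 3:
        raise InvalidWindowError(
            f"window ({window_lo}, {window_hi}) spans {len(idx)} bins; need >= 3"
        )
    best_i = -1
    best_h = -np.inf
    for j in idx[1:-1]:
        left, mid, right = vals[j - 1], vals[j], vals[j + 1]
        if mid > left and mid > right and (left - 2 * mid + right) < 0:
            if mid > best_h:  # strict >: ties keep the earlier (lower) frequency
                best_h = mid
                best_i = j
    if best_i < 0:
        return PeakResult(freq=float("nan"), height=float("nan"), found=False)
    return PeakResult(freq=float(freqs[best_i]), height=float(best_h), found=True)


def velocity_from_track(track) -> VelocitySeries:
    """Frame-by-frame speed from body-center coordinates: |d(x,y)| * fps."""
    x = np.asarray(track.x_mm, dtype=float)
    y = np.asarray(track.y_mm, dtype=float)
    if len(x) < 2:
        raise InsufficientDataError("need at least 2 frames to compute velocity")
    v = np.hypot(np.diff(x), np.diff(y)) * track.fps
    return VelocitySeries(values=v, fps=track.fps,
                          pixel_mm=getattr(track, "pixel_mm", 0.22))


def pixel_resolution(field_mm: float, pixels: int) -> float:
    """Field size divided by pixel count, at the conventional 2-decimal display
    precision (e.g. 280 mm / 1280 px -> 0.22 mm/px)."""
    if field_mm <= 0 or pixels <= 0:
        raise InvalidInputError("field_mm and pixels must be positive")
    return round(field_mm / pixels, 2)
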