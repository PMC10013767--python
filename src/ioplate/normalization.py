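"""Normalization schemes and background-subtraction fits.

Three normalizations put tremor power on an activity-adjusted scale:

* **IOP** — divide the force-plate PSD by its own integrated 40-50 Hz power
  (the plate resonance band).  Because both tremor force and overall
  momentum scale with locomotor intensity, the ratio is a severity measure
  that is stable across activity levels.  Units 1/Hz.
* **GEN** — divide a video (or accelerometer) PSD by its integrated 2-30 Hz
  (resp. 2-50 Hz) "general activity" power.
* **VEL** — divide per-epoch spectra by the video-derived body speed,
  excluding epochs not above 0.4 mm/s (guards the small denominator).

Movement spectra carry an aperiodic background that decays with frequency;
it inflates means (deflating CVs) and biases peak detection.  The fits here
remove it: a two-term exponential for accelerometer spectra (0-5 and
13-27 Hz excluded from the support), a one-term exponential for video
(0-5 Hz excluded), and shape-preserving piecewise-cubic interpolation across
the 12-27 Hz tremor band for force-plate spectra.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate, optimize, stats

from .errors import (
    DegenerateDenominatorError,
    EmptyResultError,
    FitFailureError,
    InsufficientDataError,
    InvalidBandError,
    InvalidInputError,
    InvalidWindowError,
)
from .spectral import PeakResult, Spectrogram, Spectrum, band_power, find_peak

__all__ = [
    "NormalizedSpectrum",
    "BackgroundFit",
    "SeverityResult",
    "MassCalibration",
    "IOP_BAND",
    "IOP_BAND_HIGH",
    "GEN_BANDS",
    "EXCLUDED_BANDS",
    "iop_normalize",
    "general_normalize",
    "velocity_normalize",
    "fit_background",
    "subtract_background",
    "tremor_severity",
    "mass_calibration",
]

#: Default IOP band (Hz); the plate resonance sits inside it.
IOP_BAND = (40.0, 50.0)
#: Variant used when the analysis range starts at the resonance itself.
IOP_BAND_HIGH = (42.0, 50.0)
#: General-activity denominators per channel.
GEN_BANDS = {"video": (2.0, 30.0), "accelerometer": (2.0, 50.0)}
#: Background-fit exclusion bands per channel.
EXCLUDED_BANDS = {
    "accelerometer": [(0.0, 5.0), (13.0, 27.0)],
    "video": [(0.0, 5.0)],
    "force_plate": [(12.0, 27.0)],
}
#: Upper end of exponential-fit support (Hz).
FIT_SUPPORT_MAX = 50.0


@dataclass
class NormalizedSpectrum:
    """PSD divided by a band-integrated (or velocity) denominator.

    ``values`` is 1-D for whole-record spectra or 2-D (epochs x freqs) when
    built from a spectrogram, with one denominator per epoch.
    """

    freqs: np.ndarray
    values: np.ndarray
    mode: str  # IOP | GEN | VEL
    denominator: float | np.ndarray
    bands: dict
    df: float
    epoch_times: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.values = np.asarray(self.values, dtype=float)

    @property
    def psd(self) -> np.ndarray:  # duck-types as a Spectrum for band/peak ops
        return self.values

    def epoch(self, i: int) -> "NormalizedSpectrum":
        if self.values.ndim != 2:
            raise InvalidInputError("not an epoch-resolved normalized spectrum")
        denom = np.asarray(self.denominator)[i]
        return NormalizedSpectrum(
            self.freqs, self.values[i], self.mode, float(denom), dict(self.bands),
            self.df, None, dict(self.meta),
        )


@dataclass
class BackgroundFit:
    """A fitted aperiodic background on a spectrum grid."""

    model: str  # two_term_exp | one_term_exp | shape_preserving_interp
    params: dict
    excluded_bands: list
    freqs: np.ndarray
    fitted_values: np.ndarray
    support_mask: np.ndarray


@dataclass
class SeverityResult:
    """Tremor severity scalar (1/Hz for IOP mode) with peak provenance."""

    value: float
    peak: PeakResult
    from_peak: bool  # False -> window mean fallback (flagged)


@dataclass
class MassCalibration:
    """Linear fit of 1/f^2 against added mass: stiffness and baseline mass."""

    stiffness_N_per_m: float
    baseline_mass_kg: float
    slope: float  # s^2 per kg
    intercept: float  # s^2
    r: float
    ci95: tuple
    n: int

    def predict_frequency(self, added_mass_g: float) -> float:
        inv_f2 = self.slope * added_mass_g * 1e-3 + self.intercept
        return 1.0 / math.sqrt(inv_f2)


# ---------------------------------------------------------------------------
# normalizations


def iop_normalize(spec, iop_band: tuple = IOP_BAND) -> NormalizedSpectrum:
    """Divide a spectrum (or each spectrogram epoch) by its IOP band power.

    Per-epoch division implements the same-period rule: each epoch is
    normalized by its *own* 40-50 Hz power.  Epochs with zero denominator
    are flagged in ``meta['degenerate_epochs']`` and set to NaN, never
    silently dropped.
    """
    bands = {"iop": tuple(iop_band)}
    if isinstance(spec, Spectrogram):
        denoms = np.array([band_power(spec.epoch(i), *iop_band)
                           for i in range(spec.n_epochs)])
        degenerate = np.nonzero(denoms <= 0)[0]
        values = np.where(denoms[:, None] > 0, spec.rows / np.where(
            denoms[:, None] > 0, denoms[:, None], 1.0), np.nan)
        return NormalizedSpectrum(
            spec.freqs, values, "IOP", denoms, bands, spec.df,
            epoch_times=spec.epoch_times,
            meta={**spec.meta, "degenerate_epochs": degenerate.tolist()},
        )
    denom = band_power(spec, *iop_band)
    if denom <= 0:
        raise DegenerateDenominatorError(
            f"IOP band power over {iop_band} is {denom}; cannot normalize"
        )
    return NormalizedSpectrum(spec.freqs, spec.psd / denom, "IOP", denom,
                              bands, spec.df, meta=dict(spec.meta))


def general_normalize(spec, channel: str) -> NormalizedSpectrum:
    """Divide by the channel's general-activity band power (GEN mode).

    ``channel`` is ``"video"`` (2-30 Hz) or ``"accelerometer"`` (2-50 Hz).
    """
    if channel not in GEN_BANDS:
        raise InvalidInputError(
            f"unknown channel {channel!r}; expected one of {sorted(GEN_BANDS)}"
        )
    band = GEN_BANDS[channel]
    if isinstance(spec, Spectrogram):
        denoms = np.array([band_power(spec.epoch(i), *band)
                           for i in range(spec.n_epochs)])
        if np.any(denoms <= 0):
            raise DegenerateDenominatorError("zero general-activity power in an epoch")
        values = spec.rows / denoms[:, None]
        return NormalizedSpectrum(spec.freqs, values, "GEN", denoms,
                                  {"general": band}, spec.df,
                                  epoch_times=spec.epoch_times, meta=dict(spec.meta))
    denom = band_power(spec, *band)
    if denom <= 0:
        raise DegenerateDenominatorError(
            f"general-activity power over {band} is {denom}"
        )
    return NormalizedSpectrum(spec.freqs, spec.psd / denom, "GEN", denom,
                              {"general": band}, spec.df, meta=dict(spec.meta))


def velocity_normalize(
    specgram: Spectrogram,
    epoch_velocities,
    threshold_mm_s: float = 0.4,
) -> NormalizedSpectrum:
    """Divide each epoch spectrum by its mean body speed, then average (VEL).

    Epochs whose velocity is *not over* ``threshold_mm_s`` are excluded
    (strictly-greater kept), which also guards against division by ~zero.
    The excluded count is reported in ``meta['n_excluded']``.
    """
    v = np.asarray(epoch_velocities, dtype=float)
    if len(v) != specgram.n_epochs:
        raise InvalidInputError(
            f"{len(v)} velocities for {specgram.n_epochs} epochs"
        )
    keep = v > threshold_mm_s
    if not np.any(keep):
        raise EmptyResultError(
            f"all {len(v)} epochs at or below the {threshold_mm_s} mm/s threshold"
        )
    rows = specgram.rows[keep] / v[keep, None]
    values = rows.mean(axis=0)
    return NormalizedSpectrum(
        specgram.freqs, values, "VEL", v[keep], {"threshold_mm_s": threshold_mm_s},
        specgram.df,
        meta={**specgram.meta, "n_excluded": int((~keep).sum()),
              "n_kept": int(keep.sum())},
    )


# ---------------------------------------------------------------------------
# background fitting


def _support_mask(freqs: np.ndarray, excluded, fmax: float | None) -> np.ndarray:
    mask = np.ones_like(freqs, dtype=bool)
    for lo, hi in excluded:
        mask &= ~((freqs >= lo - 1e-9) & (freqs <= hi + 1e-9))
    if fmax is not None:
        mask &= freqs <= fmax + 1e-9
    return mask


def _one_exp(f, a, b):
    return a * np.exp(b * f)


def _two_exp(f, a, b, c, d):
    return a * np.exp(b * f) + c * np.exp(d * f)


def _loglinear_init(f, y):
    """Initial (a, b) from linear regression of log y on f (positive bins)."""
    pos = y > 0
    if pos.sum() < 2:
        return max(float(np.max(y, initial=0.0)), 1e-12), 0.0
    coef = np.polyfit(f[pos], np.log(y[pos]), 1)
    return float(np.exp(coef[1])), float(min(coef[0], 0.0))


def _fit_exponential(f, y, n_terms: int):
    scale = float(np.max(y))
    if scale <= 0:
        if n_terms == 1:
            return {"a": 0.0, "b": 0.0}
        return {"a": 0.0, "b": 0.0, "c": 0.0, "d": 0.0}
    ys = y / scale
    a0, b0 = _loglinear_init(f, ys)
    attempts = []
    if n_terms == 1:
        attempts = [(a0, b0), (ys[0] if ys[0] > 0 else 1.0, -0.1), (1.0, -0.01)]
        for a_i, b_i in attempts:
            try:
                popt, _ = optimize.curve_fit(
                    _one_exp, f, ys, p0=[max(a_i, 1e-9), min(b_i, 0.0)],
                    bounds=([0.0, -np.inf], [np.inf, 0.0]), maxfev=20000,
                )
                return {"a": float(popt[0] * scale), "b": float(popt[1])}
            except (RuntimeError, ValueError):
                continue
        raise FitFailureError(
            f"one-term exponential fit failed after {len(attempts)} starts "
            f"(n={len(f)}, ymax={scale:.3g})"
        )
    # two terms: fit one, then model the residual with the second
    one = _fit_exponential(f, y, 1)
    resid = ys - _one_exp(f, one["a"] / scale, one["b"])
    c0, d0 = _loglinear_init(f, np.clip(resid, 0.0, None))
    attempts = [
        (one["a"] / scale, one["b"], max(c0, 1e-9), d0),
        (one["a"] / scale / 2, one["b"] / 2, one["a"] / scale / 2, min(2 * one["b"], 0.0)),
        (1.0, -0.01, 1.0, -0.2),
    ]
    for p0 in attempts:
        try:
            popt, _ = optimize.curve_fit(
                _two_exp, f, ys, p0=[max(p0[0], 1e-9), min(p0[1], 0.0),
                                     max(p0[2], 1e-9), min(p0[3], 0.0)],
                bounds=([0.0, -np.inf, 0.0, -np.inf], [np.inf, 0.0, np.inf, 0.0]),
                maxfev=20000,
            )
            return {"a": float(popt[0] * scale), "b": float(popt[1]),
                    "c": float(popt[2] * scale), "d": float(popt[3])}
        except (RuntimeError, ValueError):
            continue
    raise FitFailureError(
        f"two-term exponential fit failed after {len(attempts)} starts "
        f"(n={len(f)}, ymax={scale:.3g})"
    )


def fit_background(spectrum, channel: str) -> BackgroundFit:
    """Fit the aperiodic background of a spectrum for the given channel.

    * ``accelerometer`` — two-term exponential a e^(bf) + c e^(df), decaying
      terms only, excluding 0-5 Hz and the 13-27 Hz tremor band; support up
      to 50 Hz.
    * ``video`` — one-term exponential, excluding 0-5 Hz; support up to 50 Hz.
    * ``force_plate`` — shape-preserving piecewise-cubic (pchip)
      interpolation across the excluded 12-27 Hz band from flanking bins.

    Excluded bins never enter the fit support, so perturbing the spectrum
    inside an excluded band cannot change the fitted parameters.
    """
    if channel not in EXCLUDED_BANDS:
        raise InvalidInputError(
            f"unknown channel {channel!r}; expected one of {sorted(EXCLUDED_BANDS)}"
        )
    freqs = np.asarray(spectrum.freqs, dtype=float)
    vals = np.asarray(getattr(spectrum, "psd", None) if hasattr(spectrum, "psd")
                      else spectrum.values, dtype=float)
    if vals.ndim != 1:
        raise InvalidInputError("fit_background expects a 1-D spectrum")
    excluded = EXCLUDED_BANDS[channel]
    fmax = None if channel == "force_plate" else FIT_SUPPORT_MAX
    mask = _support_mask(freqs, excluded, fmax)
    if mask.sum() < 4:
        raise InsufficientDataError("too few bins outside the excluded bands")
    f_s, y_s = freqs[mask], vals[mask]

    if channel == "force_plate":
        interp = interpolate.PchipInterpolator(f_s, y_s, extrapolate=True)
        fitted = np.clip(interp(freqs), 0.0, None)
        params = {"knots_f": f_s, "knots_y": y_s}
        model = "shape_preserving_interp"
    elif channel == "accelerometer":
        params = _fit_exponential(f_s, y_s, 2)
        fitted = np.clip(_two_exp(freqs, params["a"], params["b"],
                                  params["c"], params["d"]), 0.0, None)
        model = "two_term_exp"
    else:
        params = _fit_exponential(f_s, y_s, 1)
        fitted = np.clip(_one_exp(freqs, params["a"], params["b"]), 0.0, None)
        model = "one_term_exp"
    return BackgroundFit(model=model, params=params, excluded_bands=list(excluded),
                         freqs=freqs, fitted_values=fitted, support_mask=mask)


def subtract_background(spectrum, fit: BackgroundFit):
    """Subtract a fitted background, flooring at zero (PSD stays non-negative).

    Returns an object of the same type as the input, tagged
    ``background_subtracted`` in its metadata.
    """
    freqs = np.asarray(spectrum.freqs, dtype=float)
    if freqs.shape != fit.freqs.shape or not np.allclose(freqs, fit.freqs):
        raise InvalidInputError("spectrum and fit are on different frequency grids")
    if isinstance(spectrum, NormalizedSpectrum):
        vals = np.clip(spectrum.values - fit.fitted_values, 0.0, None)
        return NormalizedSpectrum(
            freqs, vals, spectrum.mode, spectrum.denominator, dict(spectrum.bands),
            spectrum.df, spectrum.epoch_times,
            meta={**spectrum.meta, "background_subtracted": fit.model},
        )
    vals = np.clip(spectrum.psd - fit.fitted_values, 0.0, None)
    return Spectrum(freqs, vals, spectrum.df,
                    meta={**spectrum.meta, "background_subtracted": fit.model})


# ---------------------------------------------------------------------------
# severity and mass calibration


def tremor_severity(norm_spectrum, tremor_window: tuple = (15.0, 25.0)) -> SeverityResult:
    """Severity = normalized PSD at the concave peak inside the tremor window.

    When no peak is found the window mean is returned instead and the result
    is flagged (``from_peak=False``) — the value then reflects background
    level, not a tremor.  Units 1/Hz for IOP-normalized input.
    """
    freqs = np.asarray(norm_spectrum.freqs, dtype=float)
    if tremor_window[0] < freqs[0] - 1e-9 or tremor_window[1] > freqs[-1] + 1e-9:
        raise InvalidWindowError(f"tremor window {tremor_window} outside grid")
    peak = find_peak(norm_spectrum, *tremor_window)
    if peak.found:
        return SeverityResult(value=peak.height, peak=peak, from_peak=True)
    vals = np.asarray(getattr(norm_spectrum, "psd"), dtype=float)
    mask = (freqs >= tremor_window[0] - 1e-9) & (freqs <= tremor_window[1] + 1e-9)
    return SeverityResult(value=float(vals[mask].mean()), peak=peak, from_peak=False)


def mass_calibration(added_masses_g, measured_freqs_hz) -> MassCalibration:
    """Fit 1/f^2 against added mass to recover stiffness and baseline mass.

    From f = (1/2 pi) sqrt(k / (m0 + dm)):  1/f^2 = (4 pi^2 / k) dm +
    4 pi^2 m0 / k, so the OLS slope gives k and the intercept gives m0.
    Pearson r comes with its Fisher-z 95% confidence interval.
    """
    m = np.asarray(added_masses_g, dtype=float) * 1e-3  # kg
    fr = np.asarray(measured_freqs_hz, dtype=float)
    if len(m) != len(fr):
        raise InvalidInputError("masses and frequencies must have equal length")
    if len(m) < 3:
        raise InsufficientDataError(f"need >= 3 mass points, got {len(m)}")
    if np.any(fr <= 0):
        raise InvalidInputError("frequencies must be positive")
    y = 1.0 / fr**2
    res = stats.linregress(m, y)
    slope, intercept = res.slope, res.intercept
    k = 4.0 * math.pi**2 / slope if slope > 0 else float("nan")
    m0 = intercept * k / (4.0 * math.pi**2) if slope > 0 else float("nan")
    r = float(res.rvalue)
    n = len(m)
    if abs(r) >= 1.0:
        ci = (r, r)
    else:
        z = math.atanh(r)
        se = 1.0 / math.sqrt(n - 3)
        ci = (math.tanh(z - 1.959963984540054 * se),
              math.tanh(z + 1.959963984540054 * se))
    return MassCalibration(stiffness_N_per_m=k, baseline_mass_kg=m0,
                           slope=float(slope), intercept=float(intercept),
                           r=r, ci95=ci, n=n)
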