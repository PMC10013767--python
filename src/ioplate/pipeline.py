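"""End-to-end analysis chains used by the CLI and evaluation scripts.

These compose the spectral, normalization and consistency primitives into
the per-channel workflows: PSD -> normalize -> (optional) background
subtraction -> peak rule -> severity, whole-record or per-epoch.
"""

from __future__ import annotations

import numpy as np

from . import normalization as norm
from . import spectral

__all__ = [
    "analyze_force_plate",
    "epoch_severities",
    "epoch_band_powers",
]

TREMOR_WINDOW = (15.0, 25.0)


def analyze_force_plate(
    voltage,
    window_s: float = 1.0,
    iop_band: tuple = norm.IOP_BAND,
    tremor_window: tuple = TREMOR_WINDOW,
    subtract: bool = True,
) -> dict:
    """Whole-record force-plate pipeline.

    Returns a dict with the raw ``spectrum``, IOP-``normalized`` spectrum,
    the background ``fit`` and ``corrected`` spectrum (when ``subtract``),
    the tremor ``severity`` (:class:`~ioplate.normalization.SeverityResult`)
    and the detected tremor ``peak``.
    """
    spectrum = spectral.welch_psd(voltage, window_s=window_s)
    normalized = norm.iop_normalize(spectrum, iop_band=iop_band)
    out = {"spectrum": spectrum, "normalized": normalized}
    target = normalized
    if subtract:
        fit = norm.fit_background(normalized, "force_plate")
        target = norm.subtract_background(normalized, fit)
        out["fit"] = fit
        out["corrected"] = target
    severity = norm.tremor_severity(target, tremor_window=tremor_window)
    out["severity"] = severity
    out["peak"] = severity.peak
    return out


def epoch_severities(
    voltage,
    epoch_s: float = 2.0,
    iop_band: tuple = norm.IOP_BAND,
    tremor_window: tuple = TREMOR_WINDOW,
    subtract: bool = False,
) -> tuple[np.ndarray, "spectral.Spectrogram"]:
    """Per-epoch IOP-normalized tremor severities for split-half CV analysis."""
    sgram = spectral.spectrogram(voltage, epoch_s=epoch_s)
    normalized = norm.iop_normalize(sgram, iop_band=iop_band)
    sev = []
    for i in range(sgram.n_epochs):
        ep = normalized.epoch(i)
        target = ep
        if subtract:
            fit = norm.fit_background(ep, "force_plate")
            target = norm.subtract_background(ep, fit)
        sev.append(norm.tremor_severity(target, tremor_window=tremor_window).value)
    return np.asarray(sev), sgram


def epoch_band_powers(voltage, band: tuple, epoch_s: float = 2.0) -> np.ndarray:
    """Per-epoch integrated power in ``band`` (Hz)."""
    sgram = spectral.spectrogram(voltage, epoch_s=epoch_s)
    return np.array([
        spectral.band_power(sgram.epoch(i), *band) for i in range(sgram.n_epochs)
    ])
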