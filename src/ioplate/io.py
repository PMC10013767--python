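"""Plain-text file formats for traces, spectra, and configurations.

Traces are delimited text: ``#``-prefixed header lines carrying
``key: value`` metadata (channel, units, rate, seed), then tab-separated
numeric rows with a leading time column.  Plate/scenario/run configurations
are flat ``key = value`` files.  Everything round-trips at full stored
precision and stays diffable.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .errors import ParseError
from .mechanics import ForceTrace, VoltageTrace
from .scenarios import AccelTrace, TrackTrace
from .spectral import Spectrum

__all__ = [
    "write_trace",
    "read_trace",
    "write_spectrum",
    "read_spectrum",
    "write_config",
    "read_config",
]

_FMT = "%.10g"


def _header_lines(meta: dict) -> list[str]:
    return [f"# {k}: {v}" for k, v in meta.items()]


def _parse_header(path: Path) -> tuple[dict, int]:
    meta: dict = {}
    n_header = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith("#"):
                break
            n_header += 1
            body = line[1:].strip()
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = val.strip()
    if not meta:
        raise ParseError(f"{path}: no header lines found", line=1)
    return meta, n_header


def write_trace(path, trace, channel: str, units: str, seed=None) -> None:
    """Write a trace with time column(s) and a metadata header."""
    path = Path(path)
    if isinstance(trace, AccelTrace):
        fs = trace.fs_hz
        cols = np.column_stack([np.arange(len(trace.x)) / fs,
                                trace.x, trace.y, trace.z])
        colnames = "time_s x_g y_g z_g"
    elif isinstance(trace, TrackTrace):
        fs = trace.fps
        cols = np.column_stack([np.arange(len(trace.x_mm)) / fs,
                                trace.x_mm, trace.y_mm])
        colnames = "time_s x_mm y_mm"
    else:
        fs = trace.fs_hz
        cols = np.column_stack([np.arange(len(trace.values)) / fs,
                                trace.values])
        colnames = "time_s value"
    meta = {"channel": channel, "units": units, "fs_hz": fs,
            "columns": colnames}
    if seed is not None:
        meta["seed"] = seed
    if isinstance(trace, TrackTrace):
        meta["pixel_mm"] = trace.pixel_mm
    header = "\n".join(_header_lines(meta))
    np.savetxt(path, cols, fmt=_FMT, delimiter="\t", header=header, comments="")


def read_trace(path):
    """Read a trace file back into the matching trace object.

    The ``channel`` header selects the type: ``accelerometer`` ->
    :class:`AccelTrace`, ``track`` -> :class:`TrackTrace`, ``force`` ->
    :class:`ForceTrace`, anything else -> :class:`VoltageTrace`.
    """
    path = Path(path)
    meta, n_header = _parse_header(path)
    try:
        data = np.loadtxt(path, delimiter="\t", skiprows=n_header, ndmin=2)
    except ValueError as exc:
        raise ParseError(f"{path}: malformed numeric row ({exc})",
                         line=n_header + 1) from None
    if "fs_hz" not in meta:
        raise ParseError(f"{path}: header missing fs_hz")
    fs = float(meta["fs_hz"])
    channel = meta.get("channel", "voltage")
    if channel == "accelerometer":
        if data.shape[1] != 4:
            raise ParseError(f"{path}: accelerometer file needs 4 columns")
        return AccelTrace(x=data[:, 1], y=data[:, 2], z=data[:, 3], fs_hz=fs), meta
    if channel == "track":
        if data.shape[1] != 3:
            raise ParseError(f"{path}: track file needs 3 columns")
        return TrackTrace(x_mm=data[:, 1], y_mm=data[:, 2], fps=fs,
                          pixel_mm=float(meta.get("pixel_mm", 0.22))), meta
    if data.shape[1] != 2:
        raise ParseError(f"{path}: trace file needs 2 columns")
    if channel == "force":
        return ForceTrace(values=data[:, 1], fs_hz=fs), meta
    return VoltageTrace(values=data[:, 1], fs_hz=fs), meta


def write_spectrum(path, spectrum, extra_meta: dict | None = None) -> None:
    """Write a (normalized) spectrum as ``freq_hz<TAB>psd`` rows."""
    path = Path(path)
    vals = np.asarray(getattr(spectrum, "psd"), dtype=float)
    meta = {"df": spectrum.df, "columns": "freq_hz psd"}
    mode = getattr(spectrum, "mode", None)
    if mode:
        meta["mode"] = mode
    for k, v in {**getattr(spectrum, "meta", {}), **(extra_meta or {})}.items():
        if isinstance(v, (str, int, float, bool)):
            meta[k] = v
    header = "\n".join(_header_lines(meta))
    cols = np.column_stack([spectrum.freqs, vals])
    np.savetxt(path, cols, fmt=_FMT, delimiter="\t", header=header, comments="")


def read_spectrum(path) -> tuple[Spectrum, dict]:
    path = Path(path)
    meta, n_header = _parse_header(path)
    try:
        data = np.loadtxt(path, delimiter="\t", skiprows=n_header, ndmin=2)
    except ValueError as exc:
        raise ParseError(f"{path}: malformed numeric row ({exc})",
                         line=n_header + 1) from None
    if data.shape[1] != 2:
        raise ParseError(f"{path}: spectrum file needs 2 columns")
    df = float(meta.get("df", data[1, 0] - data[0, 0] if len(data) > 1 else 1.0))
    return Spectrum(freqs=data[:, 0], psd=data[:, 1], df=df, meta=meta), meta


def write_config(path, config: dict) -> None:
    """Write a flat key = value configuration file."""
    with open(path, "w") as fh:
        for key, val in config.items():
            fh.write(f"{key} = {val}\n")


def _coerce(text: str):
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            pass
    if text.lower() in ("true", "false"):
        return text.lower() == "true"
    return text


def read_config(path) -> dict:
    """Read a flat key = value file with int/float/bool coercion."""
    out: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ParseError(f"{path}: expected 'key = value'", line=lineno)
            key, _, val = line.partition("=")
            out[key.strip()] = _coerce(val.strip())
    return out
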