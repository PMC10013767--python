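"""Exception hierarchy for ioplate.

All errors derive from :class:`IoplateError` (itself a ``ValueError``) so
callers can catch package errors with one clause while plain ``ValueError``
semantics are preserved for generic code.
"""


class IoplateError(ValueError):
    """Base class for all ioplate errors."""


class InvalidConfigError(IoplateError):
    """A plate or scenario configuration violates its invariants."""


class InvalidInputError(IoplateError):
    """An input trace or array is malformed (NaN, length mismatch, ...)."""


class InsufficientDataError(IoplateError):
    """Not enough samples/epochs/points for the requested computation."""


class InvalidBandError(IoplateError):
    """A frequency band is empty or lies outside the spectrum grid."""


class InvalidWindowError(IoplateError):
    """A peak-search window is too narrow or outside the grid."""


class DegenerateDenominatorError(IoplateError):
    """A normalization denominator is zero or non-positive."""


class EmptyResultError(IoplateError):
    """Every epoch was excluded; nothing remains to analyze."""


class FitFailureError(IoplateError):
    """A background fit failed to converge after multiple restarts."""


class ParseError(IoplateError):
    """A trace/spectrum/config file could not be parsed."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
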