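"""Exception hierarchy for the inter-scale power correlation test.

Every error raised by the pipeline derives from :class:`ISPCError`.  When an
error escapes :func:`ispc.testing.run_ispc_test` it carries a ``stage``
attribute naming the pipeline stage that failed (``"preprocess"``, ``"cwt"``,
``"spectrum"``, ``"nulls"`` or ``"testing"``).
"""

from __future__ import annotations


class ISPCError(Exception):
    """Base class for all package errors."""

    #: pipeline stage that raised the error; filled in by run_ispc_test
    stage: str | None = None


class NoClipPointError(ISPCError):
    """No end sample returns close enough to the first sample.

    Signals that the input is outside the supported signal class (typically a
    strongly monotonous trend such as an exponential ramp): the clipped
    remnant would be too short for a meaningful wavelet decomposition.
    """


class TooShortError(ISPCError):
    """Signal is shorter than the smallest standard length bucket."""


class SignalTooShortError(ISPCError):
    """Signal too short to support at least two octaves of scales."""


class InvalidParamsError(ISPCError):
    """Invalid wavelet or configuration parameters."""


class NothingRetainedError(ISPCError):
    """No scale keeps the required fraction of samples inside the COI."""


class DegenerateScaleError(ISPCError):
    """A power scale has zero variance over the analysis window."""


class GridMismatchError(ISPCError):
    """Null and data matrices were built on different scale grids."""


class ZeroVarianceError(ISPCError):
    """A null distribution has zero variance for a tested pair."""


class InvalidAlphaError(ISPCError):
    """FDR level outside the open interval (0, 1)."""


class AliasError(ISPCError):
    """A requested harmonic exceeds the Nyquist frequency."""


#: CLI exit codes, one per error class (0 = success, 1 = unexpected error).
EXIT_CODES: dict[type, int] = {
    NoClipPointError: 3,
    TooShortError: 4,
    SignalTooShortError: 5,
    InvalidParamsError: 6,
    NothingRetainedError: 7,
    DegenerateScaleError: 8,
    GridMismatchError: 9,
    ZeroVarianceError: 10,
    InvalidAlphaError: 11,
    AliasError: 12,
}


def exit_code_for(exc: BaseException) -> int:
    """Map an exception to the CLI exit code for its class."""
    for cls, code in EXIT_CODES.items():
        if isinstance(exc, cls):
            return code
    if isinstance(exc, (OSError, FileNotFoundError)):
        return 2
    return 1
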