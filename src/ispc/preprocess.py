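"""Input validation, clipping and length standardization.

The significance test phase-randomizes each wavelet power scale, which
implicitly treats every series as one period of a cyclic signal.  To lessen
the cyclic-discontinuity edge artefact, the raw signal is clipped so that its
last kept sample is close to its first sample, and then zero-meaned
(:func:`clip_to_cycle`).  Strongly monotonous signals admit no such clip
point and are rejected: they are outside the class the test supports.

Long recordings can optionally be truncated to a standard length bucket
(:func:`standardize_length`) so that the expensive white-noise null can be
computed once per bucket and shared across recordings.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .exceptions import NoClipPointError, TooShortError

__all__ = [
    "Signal",
    "PreconditionReport",
    "clip_to_cycle",
    "standardize_length",
    "check_preconditions",
    "read_signal",
    "write_signal",
]


@dataclass(frozen=True)
class Signal:
    """A uniformly sampled real-valued time series.

    Parameters
    ----------
    samples:
        Sample values (arbitrary units).  Stored as a float64 array.
    fs:
        Sampling rate in Hz; must be positive.
    meta:
        Free-form label used in reports and file headers.
    """

    samples: np.ndarray
    fs: float
    meta: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size < 2:
            raise ValueError("signal must be a 1-D array with at least 2 samples")
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")

    @property
    def n(self) -> int:
        """Number of samples."""
        return self.samples.size

    @property
    def duration(self) -> float:
        """Duration in seconds (n / fs)."""
        return self.n / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.n) / self.fs

    def require_finite(self) -> None:
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("signal contains non-finite samples")


@dataclass(frozen=True)
class PreconditionReport:
    """Diagnostic flags for the signal conditions the test assumes.

    ``finite`` and ``finite_energy`` are proxies for the Dirichlet /
    integrability conditions the Fourier machinery needs; ``has_clip_point``
    reports whether the cyclic clip step can succeed.  All checks are
    advisory except where a later stage would be impossible.
    """

    finite: bool
    finite_energy: bool
    has_clip_point: bool
    clip_retained_frac: float
    n: int
    fs: float

    @property
    def passed(self) -> bool:
        return self.finite and self.finite_energy and self.has_clip_point


def _clip_tolerance(x: np.ndarray, tol_frac: float, reference: str) -> float:
    # a numerical floor (1e-9 of the median magnitude) lets exact-zero
    # anchors (e.g. Hanning endpoints, sinusoid zero crossings) admit
    # float-round-off-level matches without loosening the test otherwise
    floor = 1e-9 * float(np.median(np.abs(x)))
    if reference == "start":
        head = x[: max(16, x.size // 20)]
        return tol_frac * float(np.max(head) - np.min(head)) + floor
    if reference == "range":
        return tol_frac * float(np.max(x) - np.min(x)) + floor
    if reference == "first":
        return tol_frac * abs(float(x[0])) + floor
    raise ValueError(f"unknown clip reference {reference!r}")


def _last_clip_index(x: np.ndarray, tol: float) -> int:
    """Largest index k2 with |x[k2] - x[0]| <= tol (k2 = 0 always qualifies)."""
    ok = np.abs(x - x[0]) <= tol
    return int(x.size - 1 - np.argmax(ok[::-1]))


def clip_to_cycle(
    sig: Signal,
    tol_frac: float = 0.01,
    min_retained_frac: float = 0.5,
    reference: str = "start",
) -> Signal:
    """Clip the end of the signal so it closes near its first sample, then zero-mean.

    The signal is truncated at the largest index ``k2`` such that
    ``|x[k2] - x[0]| <= tol``.  The scale for "close to the first sample" is
    set by ``reference``: the peak-to-peak range of the initial 5% of the
    signal (``"start"``, the default), ``|x[0]|`` itself (``"first"``), or
    the global peak-to-peak range (``"range"``).  The start-local reference
    is the default because a global range degenerates for strongly
    monotonous signals (their range dwarfs any local variation, so nothing
    is ever rejected), while ``|x[0]|`` degenerates when the signal happens
    to start near zero; measuring "approximately equal" against the
    variability around the start handles both, and is what rejects e.g. an
    exponential ramp as unsupported.  The retained segment is then
    zero-meaned.

    Raises
    ------
    NoClipPointError
        If the retained segment would be shorter than
        ``min_retained_frac`` of the input.  This marks the signal class as
        unsupported (e.g. strongly monotonous trends).
    """
    if not 0.0 < tol_frac < 1.0:
        raise ValueError("tol_frac must lie in (0, 1)")
    sig.require_finite()
    x = sig.samples
    tol = _clip_tolerance(x, tol_frac, reference)
    k2 = _last_clip_index(x, tol)
    retained = k2 + 1
    if retained < min_retained_frac * sig.n:
        raise NoClipPointError(
            f"no clip point: only {retained}/{sig.n} samples would be retained "
            f"(minimum fraction {min_retained_frac}); the signal is likely "
            "strongly monotonous and unsupported by this test"
        )
    kept = x[:retained]
    return Signal(kept - kept.mean(), sig.fs, sig.meta)


#: standard length buckets in seconds, matching the null-reuse scheme
DEFAULT_BUCKETS: tuple[float, ...] = (350.0, 400.0, 500.0)


def standardize_length(
    sig: Signal,
    buckets: tuple[float, ...] = DEFAULT_BUCKETS,
    strict: bool = False,
) -> Signal:
    """Truncate a signal (from the end) to the largest bucket duration it covers.

    With the default buckets, a recording of at least 500 s becomes exactly
    500 s, one in [400, 500) s becomes 400 s, and one in [350, 400) s becomes
    350 s.  Shorter signals pass through unchanged in lenient mode (the
    default, appropriate for synthetic inputs) or raise :class:`TooShortError`
    in strict mode.
    """
    if not buckets:
        raise ValueError("buckets must be non-empty")
    chosen = None
    for b in sorted(buckets):
        if sig.duration >= b:
            chosen = b
    if chosen is None:
        if strict:
            raise TooShortError(
                f"duration {sig.duration:.3f}s is below the smallest bucket "
                f"{min(buckets)}s"
            )
        return sig
    n_new = int(round(sig.fs * chosen))
    return Signal(sig.samples[:n_new], sig.fs, sig.meta)


def check_preconditions(
    sig: Signal,
    clip_tol_frac: float = 0.01,
    min_retained_frac: float = 0.5,
    reference: str = "start",
) -> PreconditionReport:
    """Report whether the signal meets the conditions the test assumes.

    This never raises; it returns flags so callers can decide how to proceed.
    """
    x = sig.samples
    finite = bool(np.all(np.isfinite(x)))
    finite_energy = finite and bool(np.isfinite(np.dot(x, x)))
    has_clip = False
    retained_frac = 0.0
    if finite:
        tol = _clip_tolerance(x, clip_tol_frac, reference)
        k2 = _last_clip_index(x, tol)
        retained_frac = (k2 + 1) / sig.n
        has_clip = retained_frac >= min_retained_frac
    return PreconditionReport(
        finite=finite,
        finite_energy=finite_energy,
        has_clip_point=has_clip,
        clip_retained_frac=retained_frac,
        n=sig.n,
        fs=sig.fs,
    )


def read_signal(path: str | Path, fs: float, fmt: str = "text", meta: str = "") -> Signal:
    """Read a signal from single-column delimited text or flat little-endian
    64-bit float binary (``fmt="f64"``)."""
    path = Path(path)
    if fmt == "text":
        samples = np.loadtxt(path, dtype=np.float64, ndmin=1)
    elif fmt == "f64":
        samples = np.fromfile(path, dtype="<f8")
    else:
        raise ValueError(f"unknown signal format {fmt!r}")
    return Signal(samples, fs, meta or path.name)


def write_signal(sig: Signal, path: str | Path, fmt: str = "text") -> None:
    """Write a signal in one of the formats accepted by :func:`read_signal`."""
    path = Path(path)
    if fmt == "text":
        np.savetxt(path, sig.samples, fmt="%.17g")
    elif fmt == "f64":
        sig.samples.astype("<f8").tofile(path)
    else:
        raise ValueError(f"unknown signal format {fmt!r}")
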