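"""Wavelet power spectrum, COI filtering, and the inter-scale correlation matrix.

The wavelet power spectrum (WPS) is the elementwise squared magnitude of the
CWT coefficients.  Before correlating scales, two COI-based filters are
applied: scales with less than a minimum fraction (default 90%) of their
samples inside the cone of influence are dropped entirely, and a common time
window is trimmed so that every retained (scale, time) cell is edge-free.
Because the COI half-width grows monotonically with scale, the widest
retained scale defines that common window, and it is the widest window for
which all retained cells are valid.

The inter-scale power correlation matrix (ISPCM) is then the matrix of
time-wise Pearson correlations between all pairs of retained power scales,
computed over the common window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cwt import CWTResult, in_coi_mask
from .exceptions import DegenerateScaleError, NothingRetainedError

__all__ = [
    "WPS",
    "TrimmedWPS",
    "ISPCM",
    "compute_wps",
    "coi_trim",
    "pearson_ispcm",
    "pearson_matrix",
    "retention_from_mask",
]


@dataclass(frozen=True)
class WPS:
    """Wavelet power spectrum: nonnegative power (scales x n) plus COI mask."""

    power: np.ndarray
    center_freqs: np.ndarray
    coi_mask: np.ndarray
    fs: float
    coeffs: np.ndarray | None = None


@dataclass(frozen=True)
class TrimmedWPS:
    """WPS restricted to COI-valid scales and a common edge-free time window.

    ``time_window`` holds the inclusive (start, end) sample indices into the
    original series.  When the parent WPS kept its complex coefficients they
    are carried along (same trimming) for coefficient-domain surrogates.
    """

    power: np.ndarray
    retained_freqs: np.ndarray
    time_window: tuple[int, int]
    fs: float
    coeffs: np.ndarray | None = None

    @property
    def n_scales(self) -> int:
        return self.power.shape[0]

    @property
    def window_length(self) -> int:
        return self.power.shape[1]


@dataclass(frozen=True)
class ISPCM:
    """Symmetric matrix of inter-scale Pearson power correlations.

    Scales that were degenerate (zero variance over the window) keep their
    row/column, filled with NaN, and are listed in ``excluded``; downstream
    stages treat their pairs as untested rather than non-significant.
    """

    r: np.ndarray
    freqs: np.ndarray
    n_used: int
    excluded: tuple[int, ...] = ()


def compute_wps(res: CWTResult, keep_coeffs: bool = False) -> WPS:
    """Elementwise |W|^2 of the CWT coefficients, with the COI mask attached."""
    power = res.coeffs.real**2 + res.coeffs.imag**2
    return WPS(
        power=power,
        center_freqs=res.center_freqs,
        coi_mask=in_coi_mask(res),
        fs=res.fs,
        coeffs=res.coeffs if keep_coeffs else None,
    )


def retention_from_mask(
    coi_mask: np.ndarray, min_in_coi_frac: float
) -> tuple[np.ndarray, int, int]:
    """Retained-scale indices and the widest common edge-free window.

    A scale is retained when at least ``min_in_coi_frac`` of its samples lie
    inside the COI.  The common window is the intersection of the retained
    scales' in-COI spans: its bounds are the largest first-True and smallest
    last-True column over retained rows.
    """
    frac = coi_mask.mean(axis=1)
    keep = np.nonzero(frac >= min_in_coi_frac)[0]
    if keep.size == 0:
        raise NothingRetainedError(
            f"no scale has >= {min_in_coi_frac:.0%} of samples inside the COI"
        )
    rows = coi_mask[keep]
    first_true = rows.argmax(axis=1)
    last_true = rows.shape[1] - 1 - rows[:, ::-1].argmax(axis=1)
    k_lo = int(first_true.max())
    k_hi = int(last_true.min())
    if k_hi - k_lo + 1 < 3:
        raise NothingRetainedError("common in-COI window shorter than 3 samples")
    return keep, k_lo, k_hi


def coi_trim(wps: WPS, min_in_coi_frac: float = 0.9) -> TrimmedWPS:
    """Drop mostly-edge-affected scales and trim to the common edge-free window.

    Raises :class:`NothingRetainedError` when no scale survives the
    ``min_in_coi_frac`` filter (default 0.9, i.e. scales with less than 90%
    of samples inside the COI are removed).
    """
    keep, k_lo, k_hi = retention_from_mask(wps.coi_mask, min_in_coi_frac)
    sl = slice(k_lo, k_hi + 1)
    return TrimmedWPS(
        power=wps.power[keep, sl],
        retained_freqs=wps.center_freqs[keep],
        time_window=(k_lo, k_hi),
        fs=wps.fs,
        coeffs=None if wps.coeffs is None else wps.coeffs[keep, sl],
    )


def pearson_matrix(rows: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix between the rows of a 2-D array.

    Vectorized standardize-then-multiply evaluation of the textbook pairwise
    formula.  Rows with zero variance yield NaN rows/columns.
    """
    rows = np.asarray(rows, dtype=np.float64)
    centered = rows - rows.mean(axis=1, keepdims=True)
    norms = np.sqrt(np.einsum("ij,ij->i", centered, centered))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = centered / norms[:, None]
    r = z @ z.T
    np.clip(r, -1.0, 1.0, out=r)
    good = norms > 0
    diag = np.where(good, 1.0, np.nan)
    r[np.diag_indices_from(r)] = diag
    return r


def pearson_ispcm(
    tw: TrimmedWPS,
    raise_on_degenerate: bool = False,
    log_power: bool = False,
) -> ISPCM:
    """Inter-scale Pearson correlations of the trimmed power scales.

    Correlations are computed on raw power by default; ``log_power``
    switches to log10 power (with a floor at 1e-300 of each scale's peak to
    guard exact zeros), which emphasizes proportional rather than additive
    covariation.

    Degenerate (zero-variance) scales are reported in ``ISPCM.excluded`` and
    excluded from testing by leaving their correlations NaN; with
    ``raise_on_degenerate`` they raise :class:`DegenerateScaleError` instead.
    """
    if tw.window_length < 3:
        raise ValueError("retained window must contain at least 3 samples")
    rows = tw.power
    if log_power:
        floor = rows.max(axis=1, keepdims=True) * 1e-300
        rows = np.log10(np.maximum(rows, np.maximum(floor, 1e-300)))
    var = rows.var(axis=1)
    degenerate = tuple(int(i) for i in np.nonzero(var == 0.0)[0])
    if degenerate and raise_on_degenerate:
        raise DegenerateScaleError(
            f"zero-variance power scales at indices {degenerate}"
        )
    r = pearson_matrix(rows)
    return ISPCM(
        r=r,
        freqs=tw.retained_freqs,
        n_used=tw.window_length,
        excluded=degenerate,
    )
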