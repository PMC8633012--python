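"""Monte Carlo construction of the two-element null distribution.

A measured inter-scale power correlation can be spurious for three reasons:
the CWT oversamples the frequency domain (adjacent scales partly measure the
same frequencies, correlating them regardless of input), the CWT oversamples
the time domain (intra-scale autocorrelation), and the signal's own
non-stationarity adds further intra-scale autocorrelation.  The null is the
sum of two Monte Carlo elements that account for all three:

1. The *white-noise element* (:func:`white_noise_mean_ispcm`): the mean
   inter-scale correlation matrix rho_bar over L independent white-noise
   draws pushed through the same CWT/COI/correlation path as the data.  With
   uncorrelated input power, the mean isolates the frequency-oversampling
   bias of the transform itself.

2. The *phase-randomization element* (:func:`phase_rand_null`): each scale
   of the data's trimmed power spectrum is independently phase-randomized H
   times; the correlation matrices of the surrogates give a per-pair mean
   phi_bar (approximately zero) and variance Var(phi), the spread expected
   from intra-scale autocorrelation alone.

The combined null for pair (a, b) is Normal(rho_bar + phi_bar, Var(phi)).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import fft as sfft
from scipy import stats

from .cwt import CWTPlan, MorseParams, scale_grid, efold_time_per_scale
from .exceptions import GridMismatchError
from .spectrum import TrimmedWPS, pearson_matrix, retention_from_mask
from .surrogates import SurrogateConfig, ft_phase_randomize, iaaft_phase_randomize

__all__ = [
    "WhiteNoiseNull",
    "PhaseRandNull",
    "NullModel",
    "NormalityReport",
    "white_noise_mean_ispcm",
    "phase_rand_null",
    "combine_null",
    "normality_diagnostics",
    "null_grid",
    "cached_white_noise_null",
]


@dataclass(frozen=True)
class WhiteNoiseNull:
    """Mean white-noise inter-scale correlation matrix (frequency-oversampling bias)."""

    rho_bar: np.ndarray
    freqs: np.ndarray
    L: int
    noise_kind: str
    seed: int
    n: int
    fs: float


@dataclass(frozen=True)
class PhaseRandNull:
    """Per-pair mean and variance of the phase-randomized correlation null."""

    phi_bar: np.ndarray
    phi_var: np.ndarray
    freqs: np.ndarray
    H: int
    seed: int
    method: str
    domain: str
    samples: np.ndarray | None = None


@dataclass(frozen=True)
class NullModel:
    """Combined per-pair normal null: mean rho_bar + phi_bar, variance Var(phi)."""

    mean: np.ndarray
    var: np.ndarray
    freqs: np.ndarray
    provenance: dict


def null_grid(
    n: int, fs: float, params: MorseParams, min_in_coi_frac: float = 0.9
) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Retained scales, frequencies and common COI window for a length-n signal.

    Deterministic in (n, fs, wavelet params, COI rule), so data and null
    paths land on identical grids by construction.
    """
    scales, freqs = scale_grid(n, fs, params)
    t_e = efold_time_per_scale(params.gamma, params.beta) * scales
    d = np.minimum(np.arange(n), n - 1 - np.arange(n))
    mask = t_e[:, None] <= d[None, :]
    keep, k_lo, k_hi = retention_from_mask(mask, min_in_coi_frac)
    return scales[keep], freqs[keep], k_lo, k_hi


def white_noise_mean_ispcm(
    n: int,
    fs: float,
    params: MorseParams | None = None,
    L: int = 250,
    noise_kind: str = "gaussian",
    seed: int = 0,
    min_in_coi_frac: float = 0.9,
) -> WhiteNoiseNull:
    """Mean inter-scale power correlation matrix of L white-noise draws.

    Each draw is zero-meaned, wavelet-transformed on the retained scale grid
    for (n, fs), trimmed to the common COI window, and correlated; the
    elementwise mean over draws is returned.  Draws are not clipped: white
    noise has no cyclic-discontinuity structure to remove, and a fixed length
    guarantees an identical scale grid in every iteration.

    ``noise_kind`` is ``"gaussian"`` (standard normal, default) or
    ``"uniform"`` (uniform on [0, 1], zero-meaned); correlations are
    scale-free so the choice is second-order.
    """
    params = params or MorseParams()
    if L < 2:
        raise ValueError("L must be >= 2")
    if noise_kind not in ("gaussian", "uniform"):
        raise ValueError(f"unknown noise kind {noise_kind!r}")
    scales, freqs, k_lo, k_hi = null_grid(n, fs, params, min_in_coi_frac)
    plan = CWTPlan(scales, n, fs, params)
    acc = np.zeros((freqs.size, freqs.size))
    for child in np.random.SeedSequence(seed).spawn(L):
        rng = np.random.default_rng(child)
        if noise_kind == "gaussian":
            x = rng.standard_normal(n)
        else:
            x = rng.random(n)
        x = x - x.mean()
        power = plan.power(x)[:, k_lo : k_hi + 1]
        acc += pearson_matrix(power)
    rho_bar = acc / L
    # enforce exact symmetry and unit diagonal against float round-off
    rho_bar = 0.5 * (rho_bar + rho_bar.T)
    rho_bar[np.diag_indices_from(rho_bar)] = 1.0
    return WhiteNoiseNull(
        rho_bar=rho_bar,
        freqs=freqs,
        L=L,
        noise_kind=noise_kind,
        seed=seed,
        n=n,
        fs=fs,
    )


def phase_rand_null(
    tw: TrimmedWPS,
    H: int = 150,
    surrogate: SurrogateConfig | None = None,
    seed: int = 0,
    keep_samples: bool = False,
) -> PhaseRandNull:
    """Distribution of inter-scale correlations after per-scale phase randomization.

    Every scale of the trimmed WPS is independently randomized in each of H
    Monte Carlo iterations and the surrogate correlation matrix computed;
    the per-pair sample mean and unbiased sample variance over iterations
    are returned (and, optionally, the H raw matrices for diagnostics).

    ``H >= 30`` is recommended so mean and variance are estimated reliably.
    """
    surrogate = surrogate or SurrogateConfig()
    if H < 2:
        raise ValueError("H must be >= 2")
    u = tw.n_scales
    m = tw.window_length
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    phis = np.empty((H, u, u))
    if surrogate.domain == "coefficients":
        if tw.coeffs is None:
            raise ValueError(
                "coefficient-domain surrogates need a TrimmedWPS carrying "
                "coefficients (compute_wps(..., keep_coeffs=True))"
            )
        amp = np.abs(sfft.fft(tw.coeffs, axis=1))
        for h in range(H):
            theta = rng.uniform(0.0, 2.0 * np.pi, size=amp.shape)
            surr = sfft.ifft(amp * np.exp(1j * theta), axis=1)
            phis[h] = pearson_matrix(surr.real**2 + surr.imag**2)
    elif surrogate.method == "ft":
        f = sfft.rfft(tw.power, axis=1)
        amp = np.abs(f)
        for h in range(H):
            theta = rng.uniform(0.0, 2.0 * np.pi, size=f.shape)
            z = amp * np.exp(1j * theta)
            z[:, 0] = f[:, 0]
            if m % 2 == 0:
                z[:, -1] = f[:, -1]
            phis[h] = pearson_matrix(sfft.irfft(z, n=m, axis=1))
    else:  # iaaft on power rows
        for h in range(H):
            surr = np.empty_like(tw.power)
            for i in range(u):
                surr[i] = iaaft_phase_randomize(
                    tw.power[i], rng, max_iter=surrogate.iaaft_max_iter
                )
            phis[h] = pearson_matrix(surr)
    phi_bar = phis.mean(axis=0)
    phi_var = phis.var(axis=0, ddof=1)
    phi_bar = 0.5 * (phi_bar + phi_bar.T)
    phi_var = 0.5 * (phi_var + phi_var.T)
    return PhaseRandNull(
        phi_bar=phi_bar,
        phi_var=phi_var,
        freqs=np.asarray(tw.retained_freqs),
        H=H,
        seed=seed,
        method=surrogate.method,
        domain=surrogate.domain,
        samples=phis if keep_samples else None,
    )


def combine_null(wn: WhiteNoiseNull, pr: PhaseRandNull) -> NullModel:
    """Sum the two elements: mean = rho_bar + phi_bar, variance = Var(phi).

    Raises :class:`GridMismatchError` unless both elements were computed on
    the same retained frequency grid.
    """
    if wn.freqs.shape != pr.freqs.shape or not np.allclose(
        wn.freqs, pr.freqs, rtol=1e-10
    ):
        raise GridMismatchError(
            "white-noise and phase-randomization nulls use different scale grids"
        )
    return NullModel(
        mean=wn.rho_bar + pr.phi_bar,
        var=pr.phi_var.copy(),
        freqs=wn.freqs.copy(),
        provenance={
            "L": wn.L,
            "H": pr.H,
            "noise_kind": wn.noise_kind,
            "wn_seed": wn.seed,
            "pr_seed": pr.seed,
            "surrogate_method": pr.method,
            "surrogate_domain": pr.domain,
            "n": wn.n,
            "fs": wn.fs,
        },
    )


@dataclass(frozen=True)
class NormalityReport:
    """Per-pair normality screen of the phase-randomized null samples."""

    frac_normal: float
    n_pairs: int
    n_rejected: int
    H: int
    alpha: float
    pvalues: np.ndarray


def normality_diagnostics(pr: PhaseRandNull, alpha: float = 0.05) -> NormalityReport:
    """Test each pair's H null samples for normality, with FDR control.

    Uses the D'Agostino-Pearson omnibus test per upper-triangle pair and
    Benjamini-Hochberg FDR at ``alpha``; reports the fraction of pairs not
    rejected.  Requires ``phase_rand_null(..., keep_samples=True)``.
    """
    if pr.samples is None:
        raise ValueError("run phase_rand_null with keep_samples=True first")
    from statsmodels.stats.multitest import multipletests

    u = pr.samples.shape[1]
    iu = np.triu_indices(u, k=1)
    draws = pr.samples[:, iu[0], iu[1]]  # H x n_pairs
    # constant columns (degenerate pairs) cannot be tested
    variable = draws.std(axis=0) > 0
    pvals = np.full(draws.shape[1], np.nan)
    if variable.any():
        _, p = stats.normaltest(draws[:, variable], axis=0)
        pvals[variable] = p
    tested = pvals[np.isfinite(pvals)]
    reject, _, _, _ = multipletests(tested, alpha=alpha, method="fdr_bh")
    return NormalityReport(
        frac_normal=float(1.0 - reject.mean()) if tested.size else float("nan"),
        n_pairs=int(tested.size),
        n_rejected=int(reject.sum()),
        H=pr.H,
        alpha=alpha,
        pvalues=pvals,
    )


def _null_cache_key(
    n: int,
    fs: float,
    params: MorseParams,
    L: int,
    noise_kind: str,
    seed: int,
    min_in_coi_frac: float,
) -> str:
    payload = json.dumps(
        {
            "n": n,
            "fs": fs,
            "gamma": params.gamma,
            "beta": params.beta,
            "voices": params.voices_per_octave,
            "freq_limits": params.freq_limits,
            "L": L,
            "noise_kind": noise_kind,
            "seed": seed,
            "min_in_coi_frac": min_in_coi_frac,
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def cached_white_noise_null(
    n: int,
    fs: float,
    params: MorseParams | None = None,
    L: int = 250,
    noise_kind: str = "gaussian",
    seed: int = 0,
    min_in_coi_frac: float = 0.9,
    cache_dir: str | Path | None = None,
) -> tuple[WhiteNoiseNull, bool]:
    """White-noise null with an optional on-disk cache.

    The cache key covers every input that determines the result (length,
    rate, wavelet parameters, L, noise kind, seed, COI rule) so nulls can be
    reused across signals of a standard length.  Returns ``(null, from_cache)``.
    """
    params = params or MorseParams()
    if cache_dir is None:
        return (
            white_noise_mean_ispcm(n, fs, params, L, noise_kind, seed, min_in_coi_frac),
            False,
        )
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    key = _null_cache_key(n, fs, params, L, noise_kind, seed, min_in_coi_frac)
    path = cache_dir / f"wn_null_{key}.npz"
    if path.exists():
        data = np.load(path)
        return (
            WhiteNoiseNull(
                rho_bar=data["rho_bar"],
                freqs=data["freqs"],
                L=int(data["L"]),
                noise_kind=str(data["noise_kind"]),
                seed=int(data["seed"]),
                n=int(data["n"]),
                fs=float(data["fs"]),
            ),
            True,
        )
    wn = white_noise_mean_ispcm(n, fs, params, L, noise_kind, seed, min_in_coi_frac)
    np.savez_compressed(
        path,
        rho_bar=wn.rho_bar,
        freqs=wn.freqs,
        L=wn.L,
        noise_kind=wn.noise_kind,
        seed=wn.seed,
        n=wn.n,
        fs=wn.fs,
    )
    return wn, False
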