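"""Synthetic validation signals.

Six generators cover the qualitative regimes the significance test must
handle: narrowband stationary content (double sinusoid), transient
narrowband content (double pulse), transient frequency-modulated content
(double chirp), broadband harmonically locked content (square wave), a
strongly monotonous trend that the clipping step must reject (exponential),
and structureless noise (white noise).  Defaults follow the validation
conditions: 50 s at 1 kHz, with low-amplitude additive Gaussian noise
(standard deviation 0.05 relative to unit carrier amplitude) where noise is
part of the construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import AliasError
from .preprocess import Signal

__all__ = [
    "SyntheticSpec",
    "KINDS",
    "gen_double_sinusoid",
    "gen_double_pulse",
    "gen_double_chirp",
    "gen_square_wave",
    "gen_exponential",
    "gen_white_noise",
    "generate",
]

KINDS = (
    "double_sinusoid",
    "double_pulse",
    "double_chirp",
    "square_wave",
    "exponential",
    "white_noise",
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Shared parameters of the synthetic generators."""

    kind: str = "white_noise"
    fs: float = 1000.0
    duration: float = 50.0
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown synthetic kind {self.kind!r}")
        if self.fs <= 0 or self.duration <= 0 or self.noise_sd < 0:
            raise ValueError("fs and duration must be positive, noise_sd >= 0")

    @property
    def n(self) -> int:
        return int(round(self.fs * self.duration))

    def times(self) -> np.ndarray:
        return np.arange(self.n) / self.fs

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(self.seed))


def _noise(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.noise_sd == 0:
        return np.zeros(spec.n)
    return rng.normal(0.0, spec.noise_sd, spec.n)


def gen_double_sinusoid(
    spec: SyntheticSpec, f1: float = 10.0, f2: float = 50.0
) -> Signal:
    """Two unit sinusoids plus noise, the whole record Hanning-enveloped:
    ``(sin(2 pi f1 t) + sin(2 pi f2 t) + eps) * hann(n)``."""
    t = spec.times()
    rng = spec.rng()
    x = np.sin(2 * np.pi * f1 * t) + np.sin(2 * np.pi * f2 * t) + _noise(spec, rng)
    x *= np.hanning(spec.n)
    return Signal(x, spec.fs, meta=f"double_sinusoid(f1={f1},f2={f2})")


def gen_double_pulse(
    spec: SyntheticSpec,
    pulses: tuple[tuple[float, float, float], ...] = (
        (30.0, 10.0, 10.5),
        (5.0, 25.0, 26.5),
    ),
) -> Signal:
    """Hanning-windowed sinusoidal pulses at distinct times plus noise.

    Each pulse is ``(carrier_hz, t_start_s, t_end_s)``; defaults place a
    30 Hz pulse in [10, 10.5] s and a 5 Hz pulse in [25, 26.5] s.
    """
    t = spec.times()
    rng = spec.rng()
    x = _noise(spec, rng)
    for f, t0, t1 in pulses:
        idx = np.nonzero((t >= t0) & (t < t1))[0]
        win = np.hanning(idx.size)
        x[idx] += np.sin(2 * np.pi * f * (t[idx] - t0)) * win
    return Signal(x, spec.fs, meta="double_pulse")


def gen_double_chirp(
    spec: SyntheticSpec,
    chirps: tuple[tuple[float, float, float, float], ...] = (
        (20.0, 50.0, 10.0, 10.5),
        (1.0, 5.0, 25.0, 26.5),
    ),
) -> Signal:
    """Hanning-windowed quadratic chirps at distinct times plus noise.

    Each chirp is ``(f_start_hz, f_end_hz, t_start_s, t_end_s)``, with
    instantaneous frequency f0 + (f1 - f0) (tau/T)^2 so it sweeps
    quadratically from f0 to f1 over the interval.  The phase is the closed
    form integral 2*pi*(f0 tau + (f1 - f0) tau^3 / (3 T^2)).
    """
    t = spec.times()
    rng = spec.rng()
    x = _noise(spec, rng)
    for f0, f1, t0, t1 in chirps:
        idx = np.nonzero((t >= t0) & (t < t1))[0]
        tau = t[idx] - t0
        T = t1 - t0
        phase = 2 * np.pi * (f0 * tau + (f1 - f0) * tau**3 / (3 * T**2))
        x[idx] += np.sin(phase) * np.hanning(idx.size)
    return Signal(x, spec.fs, meta="double_chirp")


def gen_square_wave(
    spec: SyntheticSpec, f: float = 2.0, n_harmonics: int | None = None
) -> Signal:
    """Truncated odd-harmonic Fourier series of a square wave plus noise:
    ``(4/pi) * sum_j sin((2j-1) w t) / (2j-1) + eps``.

    ``n_harmonics`` counts the odd harmonics included; by default every odd
    harmonic below the Nyquist frequency.  An explicit count whose highest
    harmonic reaches Nyquist raises :class:`AliasError`.
    """
    max_fit = int(np.floor((spec.fs / 2.0 - 1e-9) / f))  # highest harmonic index
    max_fit_odd = (max_fit + 1) // 2  # number of odd harmonics below Nyquist
    if n_harmonics is None:
        n_harmonics = max_fit_odd
    if n_harmonics < 1:
        raise ValueError("n_harmonics must be >= 1")
    if (2 * n_harmonics - 1) * f >= spec.fs / 2.0:
        raise AliasError(
            f"harmonic {(2 * n_harmonics - 1) * f:g} Hz reaches the Nyquist "
            f"frequency {spec.fs / 2:g} Hz"
        )
    t = spec.times()
    rng = spec.rng()
    w = 2 * np.pi * f
    x = np.zeros(spec.n)
    for j in range(1, n_harmonics + 1):
        k = 2 * j - 1
        x += np.sin(k * w * t) / k
    x *= 4.0 / np.pi
    x += _noise(spec, rng)
    return Signal(x, spec.fs, meta=f"square_wave(f={f})")


def gen_exponential(spec: SyntheticSpec) -> Signal:
    """Exponential ramp ``exp(t) + eps``; unsupported by the test by design.

    For durations beyond ~700 s the exponent is clamped at 700 so the float64
    range is not exceeded (the tail saturates instead of overflowing).
    """
    t = np.minimum(spec.times(), 700.0)
    rng = spec.rng()
    return Signal(np.exp(t) + _noise(spec, rng), spec.fs, meta="exponential")


def gen_white_noise(spec: SyntheticSpec, kind: str = "uniform") -> Signal:
    """I.i.d. noise: ``uniform`` on [0, 1] (default, matching the validation
    signal) or standard ``gaussian``.  Zero-meaning happens downstream."""
    rng = spec.rng()
    if kind == "uniform":
        x = rng.random(spec.n)
    elif kind == "gaussian":
        x = rng.standard_normal(spec.n)
    else:
        raise ValueError(f"unknown white noise kind {kind!r}")
    return Signal(x, spec.fs, meta=f"white_noise({kind})")


def generate(spec: SyntheticSpec, **kwargs) -> Signal:
    """Dispatch to the generator named by ``spec.kind``."""
    table = {
        "double_sinusoid": gen_double_sinusoid,
        "double_pulse": gen_double_pulse,
        "double_chirp": gen_double_chirp,
        "square_wave": gen_square_wave,
        "exponential": gen_exponential,
        "white_noise": gen_white_noise,
    }
    return table[spec.kind](spec, **kwargs)
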