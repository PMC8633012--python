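"""Synthetic validation-signal generators."""

import numpy as np
import pytest
from scipy.signal import hilbert, periodogram

from ispc.exceptions import AliasError, NoClipPointError
from ispc.preprocess import check_preconditions, clip_to_cycle
from ispc.synthetic import (
    KINDS,
    SyntheticSpec,
    gen_double_chirp,
    gen_double_pulse,
    gen_double_sinusoid,
    gen_exponential,
    gen_square_wave,
    gen_white_noise,
    generate,
)

SHORT = dict(fs=500.0, duration=30.0)


class TestDoubleSinusoid:
    def test_envelope_zeros_at_ends_without_noise(self):
        sig = gen_double_sinusoid(SyntheticSpec("double_sinusoid", noise_sd=0.0, **SHORT))
        assert sig.samples[0] == pytest.approx(0.0, abs=1e-9)
        assert sig.samples[-1] == pytest.approx(0.0, abs=1e-9)

    def test_spectral_peaks_at_10_and_50_hz(self):
        sig = gen_double_sinusoid(SyntheticSpec("double_sinusoid", **SHORT))
        f, p = periodogram(sig.samples, fs=sig.fs)
        top2 = np.sort(f[np.argsort(p)[-2:]])
        assert top2 == pytest.approx([10.0, 50.0], abs=0.2)

    def test_seeds_differ_only_in_noise(self):
        a = gen_double_sinusoid(SyntheticSpec("double_sinusoid", seed=1, **SHORT))
        b = gen_double_sinusoid(SyntheticSpec("double_sinusoid", seed=2, **SHORT))
        clean = gen_double_sinusoid(
            SyntheticSpec("double_sinusoid", noise_sd=0.0, **SHORT)
        )
        assert not np.array_equal(a.samples, b.samples)
        # both deviate from the clean signal by bounded envelope-scaled noise
        for s in (a, b):
            dev = s.samples - clean.samples
            assert np.abs(dev).max() < 0.05 * 6


class TestDoublePulse:
    def test_zero_outside_pulse_intervals_without_noise(self):
        spec = SyntheticSpec("double_pulse", noise_sd=0.0, fs=500.0, duration=30.0)
        sig = gen_double_pulse(spec)
        t = sig.times
        outside = ~(((t >= 10.0) & (t < 10.5)) | ((t >= 25.0) & (t < 26.5)))
        assert np.all(sig.samples[outside] == 0.0)
        assert np.abs(sig.samples[~outside]).max() > 0.5

    def test_pulse_carriers_at_30_and_5_hz(self):
        spec = SyntheticSpec("double_pulse", noise_sd=0.0, fs=500.0, duration=30.0)
        sig = gen_double_pulse(spec)
        t = sig.times
        for (t0, t1, f0) in [(10.0, 10.5, 30.0), (25.0, 26.5, 5.0)]:
            seg = sig.samples[(t >= t0) & (t < t1)]
            f, p = periodogram(seg, fs=sig.fs)
            assert f[p.argmax()] == pytest.approx(f0, abs=2.5)


class TestDoubleChirp:
    def _inst_freq(self, seg, fs):
        phase = np.unwrap(np.angle(hilbert(seg)))
        return np.gradient(phase) * fs / (2 * np.pi)

    def test_instantaneous_frequency_endpoints_and_monotonicity(self):
        spec = SyntheticSpec("double_chirp", noise_sd=0.0, fs=1000.0, duration=30.0)
        sig = gen_double_chirp(spec)
        t = sig.times
        seg = sig.samples[(t >= 10.0) & (t < 10.5)]
        fi = self._inst_freq(seg, sig.fs)
        core = slice(len(fi) // 10, -len(fi) // 10)  # away from window edges
        assert fi[core][0] == pytest.approx(20.0, abs=4.0)
        assert fi[core][-1] > 40.0
        # quadratic sweep: increasing inside the pulse
        smooth = np.convolve(fi[core], np.ones(25) / 25, mode="valid")
        assert np.all(np.diff(smooth) > -0.5)

    def test_zero_outside_intervals_without_noise(self):
        spec = SyntheticSpec("double_chirp", noise_sd=0.0, fs=500.0, duration=30.0)
        sig = gen_double_chirp(spec)
        t = sig.times
        outside = ~(((t >= 10.0) & (t < 10.5)) | ((t >= 25.0) & (t < 26.5)))
        assert np.all(sig.samples[outside] == 0.0)


class TestSquareWave:
    def test_single_harmonic_is_scaled_sine(self):
        spec = SyntheticSpec("square_wave", noise_sd=0.0, fs=500.0, duration=10.0)
        sig = gen_square_wave(spec, f=2.0, n_harmonics=1)
        t = sig.times
        np.testing.assert_allclose(
            sig.samples, (4 / np.pi) * np.sin(2 * np.pi * 2.0 * t), atol=1e-12
        )

    def test_harmonic_amplitude_ratios(self):
        spec = SyntheticSpec("square_wave", noise_sd=0.0, fs=500.0, duration=50.0)
        sig = gen_square_wave(spec, f=2.0, n_harmonics=3)
        f, p = periodogram(sig.samples, fs=sig.fs)
        amps = [np.sqrt(p[np.argmin(np.abs(f - h * 2.0))]) for h in (1, 3, 5)]
        assert amps[1] / amps[0] == pytest.approx(1 / 3, rel=0.05)
        assert amps[2] / amps[0] == pytest.approx(1 / 5, rel=0.05)

    def test_converges_to_ideal_square_wave(self):
        spec = SyntheticSpec("square_wave", noise_sd=0.0, fs=1000.0, duration=5.0)
        t = spec.times()
        ideal = np.sign(np.sin(2 * np.pi * 2.0 * t))
        devs = []
        for nh in (3, 10, 60):
            x = gen_square_wave(spec, f=2.0, n_harmonics=nh).samples
            core = np.abs(ideal) > 0.5  # measure away from the jumps
            devs.append(np.abs((x - ideal))[core].mean())
        assert devs[2] < devs[1] < devs[0]

    def test_alias_error_beyond_nyquist(self):
        spec = SyntheticSpec("square_wave", fs=100.0, duration=5.0)
        with pytest.raises(AliasError):
            gen_square_wave(spec, f=2.0, n_harmonics=13)  # 25th harmonic = 50 Hz

    def test_default_harmonics_fill_band_below_nyquist(self):
        spec = SyntheticSpec("square_wave", noise_sd=0.0, fs=1000.0, duration=10.0)
        sig = gen_square_wave(spec, f=2.0)
        f, p = periodogram(sig.samples, fs=sig.fs)
        # substantial energy near (but below) Nyquist
        hi = (f > 400) & (f < 500)
        assert p[hi].max() > 1e-7


class TestExponential:
    def test_starts_at_one_and_increases(self):
        spec = SyntheticSpec("exponential", noise_sd=0.0, fs=100.0, duration=10.0)
        sig = gen_exponential(spec)
        assert sig.samples[0] == pytest.approx(1.0)
        assert np.all(np.diff(sig.samples) > 0)

    def test_long_duration_saturates_instead_of_overflowing(self):
        spec = SyntheticSpec("exponential", noise_sd=0.0, fs=2.0, duration=800.0)
        sig = gen_exponential(spec)
        assert np.all(np.isfinite(sig.samples))

    def test_pipeline_rejects_it_at_the_clip_stage(self):
        from ispc.testing import RunConfig, run_ispc_test

        spec = SyntheticSpec("exponential", fs=500.0, duration=20.0, seed=3)
        with pytest.raises(NoClipPointError) as err:
            run_ispc_test(gen_exponential(spec), RunConfig(L=4, H=4))
        assert err.value.stage == "preprocess"


class TestWhiteNoise:
    def test_uniform_bounds_and_mean(self):
        spec = SyntheticSpec("white_noise", fs=1000.0, duration=20.0, seed=5)
        sig = gen_white_noise(spec, kind="uniform")
        x = sig.samples
        assert x.min() >= 0.0 and x.max() <= 1.0
        assert abs(x.mean() - 0.5) < 4.0 / np.sqrt(x.size)

    def test_lag_one_autocorrelation_near_zero(self):
        spec = SyntheticSpec("white_noise", fs=1000.0, duration=20.0, seed=5)
        x = gen_white_noise(spec).samples
        x = x - x.mean()
        rho1 = (x[:-1] @ x[1:]) / (x @ x)
        assert abs(rho1) < 4.0 / np.sqrt(x.size)

    def test_gaussian_kind(self):
        spec = SyntheticSpec("white_noise", fs=100.0, duration=10.0, seed=5)
        x = gen_white_noise(spec, kind="gaussian").samples
        assert abs(x.std() - 1.0) < 0.1


class TestGeneratorContracts:
    @pytest.mark.parametrize("kind", KINDS)
    def test_deterministic_given_spec(self, kind):
        spec = SyntheticSpec(kind, fs=500.0, duration=30.0, seed=11)
        a, b = generate(spec), generate(spec)
        np.testing.assert_array_equal(a.samples, b.samples)

    @pytest.mark.parametrize("kind", [k for k in KINDS if k != "exponential"])
    def test_all_but_exponential_pass_preprocessing(self, kind):
        spec = SyntheticSpec(kind, fs=500.0, duration=30.0, seed=11)
        sig = generate(spec)
        assert check_preconditions(sig).passed
        clipped = clip_to_cycle(sig)
        assert clipped.n > 0.5 * sig.n

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            SyntheticSpec("triangle_wave")
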