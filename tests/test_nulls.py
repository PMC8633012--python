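"""White-noise and phase-randomization null construction."""

import numpy as np
import pytest
from scipy import stats

from ispc.cwt import morse_cwt
from ispc.exceptions import GridMismatchError
from ispc.nulls import (
    NullModel,
    PhaseRandNull,
    WhiteNoiseNull,
    cached_white_noise_null,
    combine_null,
    normality_diagnostics,
    phase_rand_null,
    white_noise_mean_ispcm,
)
from ispc.preprocess import Signal
from ispc.spectrum import coi_trim, compute_wps
from ispc.surrogates import SurrogateConfig

N, FS = 3000, 500.0


@pytest.fixture(scope="module")
def small_wn_null():
    return white_noise_mean_ispcm(N, FS, L=16, seed=42)


@pytest.fixture(scope="module")
def small_trimmed():
    rng = np.random.default_rng(7)
    x = rng.standard_normal(N)
    sig = Signal(x - x.mean(), FS)
    return coi_trim(compute_wps(morse_cwt(sig), keep_coeffs=True))


class TestWhiteNoiseNull:
    def test_unit_diagonal_and_symmetry(self, small_wn_null):
        np.testing.assert_array_equal(np.diag(small_wn_null.rho_bar), 1.0)
        np.testing.assert_array_equal(small_wn_null.rho_bar, small_wn_null.rho_bar.T)
        assert np.all(np.abs(small_wn_null.rho_bar) <= 1.0)

    def test_adjacent_scales_strongly_positively_biased(self, small_wn_null):
        adj = np.diag(small_wn_null.rho_bar, k=1)
        assert adj.min() > 0.5

    def test_deterministic_given_seed(self):
        a = white_noise_mean_ispcm(1000, 250.0, L=4, seed=9)
        b = white_noise_mean_ispcm(1000, 250.0, L=4, seed=9)
        np.testing.assert_array_equal(a.rho_bar, b.rho_bar)
        c = white_noise_mean_ispcm(1000, 250.0, L=4, seed=10)
        assert not np.array_equal(a.rho_bar, c.rho_bar)

    def test_uniform_noise_kind_supported(self):
        wn = white_noise_mean_ispcm(1000, 250.0, L=4, noise_kind="uniform", seed=1)
        np.testing.assert_array_equal(np.diag(wn.rho_bar), 1.0)

    def test_cache_round_trip(self, tmp_path):
        a, hit_a = cached_white_noise_null(
            1000, 250.0, L=4, seed=3, cache_dir=tmp_path
        )
        b, hit_b = cached_white_noise_null(
            1000, 250.0, L=4, seed=3, cache_dir=tmp_path
        )
        assert not hit_a and hit_b
        np.testing.assert_array_equal(a.rho_bar, b.rho_bar)
        c, hit_c = cached_white_noise_null(
            1000, 250.0, L=4, seed=4, cache_dir=tmp_path
        )
        assert not hit_c


class TestPhaseRandNull:
    def test_samples_bounded_and_moments_consistent(self, small_trimmed):
        pr = phase_rand_null(small_trimmed, H=40, seed=3, keep_samples=True)
        assert np.all(np.abs(pr.samples) <= 1.0 + 1e-12)
        np.testing.assert_allclose(pr.phi_bar, pr.samples.mean(axis=0), atol=1e-12)
        assert np.all(pr.phi_var >= 0)

    def test_offdiagonal_mean_near_zero(self, small_trimmed):
        pr = phase_rand_null(small_trimmed, H=60, seed=3)
        u = pr.phi_bar.shape[0]
        iu = np.triu_indices(u, k=1)
        sd = np.sqrt(pr.phi_var[iu])
        # mean of H draws should sit within a few standard errors of zero
        assert np.all(np.abs(pr.phi_bar[iu]) <= 5.0 * sd / np.sqrt(pr.H) + 1e-6)

    def test_deterministic_given_seed(self, small_trimmed):
        a = phase_rand_null(small_trimmed, H=8, seed=11)
        b = phase_rand_null(small_trimmed, H=8, seed=11)
        np.testing.assert_array_equal(a.phi_bar, b.phi_bar)
        np.testing.assert_array_equal(a.phi_var, b.phi_var)

    @pytest.mark.parametrize("domain", ["power", "coefficients"])
    def test_domains_agree_on_distribution_scale(self, small_trimmed, domain):
        pr = phase_rand_null(
            small_trimmed, H=30, seed=5, surrogate=SurrogateConfig(domain=domain)
        )
        u = pr.phi_bar.shape[0]
        iu = np.triu_indices(u, k=1)
        assert np.median(np.sqrt(pr.phi_var[iu])) < 0.2

    def test_matches_independent_surrogate_construction(self, small_trimmed):
        # distribution check against a brute-force two-independent-surrogate
        # oracle for one far-separated pair
        from ispc.surrogates import ft_phase_randomize

        a, b = 0, small_trimmed.n_scales - 1
        pr = phase_rand_null(
            small_trimmed,
            H=120,
            seed=5,
            keep_samples=True,
            surrogate=SurrogateConfig(domain="power"),
        )
        phi_ab = pr.samples[:, a, b]
        rng = np.random.default_rng(99)
        brute = []
        for _ in range(120):
            sa = ft_phase_randomize(small_trimmed.power[a], rng)
            sb = ft_phase_randomize(small_trimmed.power[b], rng)
            sa = sa - sa.mean()
            sb = sb - sb.mean()
            brute.append(
                float(sa @ sb / np.sqrt((sa @ sa) * (sb @ sb)))
            )
        assert stats.ks_2samp(phi_ab, np.array(brute)).pvalue > 0.01

    def test_variance_shrinks_with_longer_window(self):
        rng = np.random.default_rng(3)
        stats_by_n = []
        for n in (2000, 8000):
            x = rng.standard_normal(n)
            tw = coi_trim(compute_wps(morse_cwt(Signal(x - x.mean(), FS))))
            pr = phase_rand_null(
                tw, H=40, seed=4, surrogate=SurrogateConfig(domain="power")
            )
            u = pr.phi_var.shape[0]
            iu = np.triu_indices(u, k=1)
            stats_by_n.append(np.median(pr.phi_var[iu]))
        assert stats_by_n[1] < stats_by_n[0]


class TestCombineNull:
    def test_toy_arithmetic(self):
        freqs = np.array([8.0, 4.0, 2.0])
        rho = np.array([[1.0, 0.5, 0.1], [0.5, 1.0, 0.4], [0.1, 0.4, 1.0]])
        phib = np.array([[1.0, 0.02, -0.01], [0.02, 1.0, 0.03], [-0.01, 0.03, 1.0]])
        phiv = np.full((3, 3), 0.04)
        wn = WhiteNoiseNull(rho, freqs, L=10, noise_kind="gaussian", seed=0, n=100, fs=10.0)
        pr = PhaseRandNull(phib, phiv, freqs, H=20, seed=0, method="ft", domain="power")
        null = combine_null(wn, pr)
        assert null.mean[0, 1] == pytest.approx(0.52)
        assert null.mean[0, 2] == pytest.approx(0.09)
        assert null.var[1, 2] == pytest.approx(0.04)
        assert null.provenance["L"] == 10 and null.provenance["H"] == 20

    def test_zero_rho_means_phase_mean_only(self):
        freqs = np.array([4.0, 2.0])
        rho = np.eye(2)
        rho[0, 1] = rho[1, 0] = 0.0
        phib = np.array([[1.0, 0.3], [0.3, 1.0]])
        wn = WhiteNoiseNull(rho, freqs, 2, "gaussian", 0, 10, 1.0)
        pr = PhaseRandNull(phib, np.full((2, 2), 0.1), freqs, 2, 0, "ft", "power")
        null = combine_null(wn, pr)
        assert null.mean[0, 1] == pytest.approx(phib[0, 1])

    def test_grid_mismatch_raises(self):
        wn = WhiteNoiseNull(np.eye(2), np.array([4.0, 2.0]), 2, "gaussian", 0, 10, 1.0)
        pr = PhaseRandNull(
            np.eye(3), np.ones((3, 3)), np.array([4.0, 2.0, 1.0]), 2, 0, "ft", "power"
        )
        with pytest.raises(GridMismatchError):
            combine_null(wn, pr)


class TestNormalityDiagnostics:
    def _null_with_samples(self, draws, freqs=None):
        H, u, _ = draws.shape
        freqs = freqs if freqs is not None else np.geomspace(32, 1, u)
        return PhaseRandNull(
            phi_bar=draws.mean(axis=0),
            phi_var=draws.var(axis=0, ddof=1),
            freqs=freqs,
            H=H,
            seed=0,
            method="ft",
            domain="power",
            samples=draws,
        )

    def test_gaussian_draws_mostly_pass(self):
        rng = np.random.default_rng(0)
        draws = rng.standard_normal((200, 10, 10)) * 0.05
        report = normality_diagnostics(self._null_with_samples(draws), alpha=0.05)
        assert report.frac_normal >= 0.95
        assert report.H == 200

    def test_skewed_draws_mostly_fail(self):
        rng = np.random.default_rng(0)
        draws = rng.exponential(1.0, (200, 10, 10))
        report = normality_diagnostics(self._null_with_samples(draws), alpha=0.05)
        assert report.frac_normal < 0.5

    def test_requires_samples(self, small_trimmed):
        pr = phase_rand_null(small_trimmed, H=8, seed=1)
        with pytest.raises(ValueError):
            normality_diagnostics(pr)
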