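"""Noise-model tests: closed-form oracles for the multi-coil magnitude PDF,
quadrature/bisection oracles for the CDF and RC cutoff, sigma estimation,
and the Gaussian-approximation comparison."""

import math

import numpy as np
import pytest
from scipy import integrate

from lgequant import (
    IntensityHistogram,
    NoiseModel,
    estimate_sigma,
    fit_gaussian_to_histogram,
    gaussian_vs_measured_test,
    rayleigh_cdf,
    rayleigh_pdf,
    rc_threshold,
)
from lgequant.errors import (
    DegenerateBackgroundError,
    DegenerateDifferenceError,
    InsufficientDataError,
    ParameterError,
    SaturatedNoiseError,
)
from lgequant.noise import chi_mean_factor, chi_sd_factor, rc_quantile

from conftest import sos_magnitude


def explicit_pdf(m, sigma, coils):
    """The magnitude-noise density written out longhand in log space:
    m^(2K-1) / (2^(K-1) sigma^(2K) (K-1)!) * exp(-m^2 / 2 sigma^2)."""
    m = np.asarray(m, dtype=float)
    out = np.zeros_like(m)
    pos = m > 0
    k = coils
    logp = (
        (2 * k - 1) * np.log(m[pos])
        - (k - 1) * math.log(2.0)
        - 2 * k * math.log(sigma)
        - math.lgamma(k)
        - m[pos] ** 2 / (2.0 * sigma**2)
    )
    out[pos] = np.exp(logp)
    return out


class TestRayleighPdf:
    def test_zero_for_negative_and_zero_intensity(self, model_k8):
        assert rayleigh_pdf(-1.0, model_k8) == 0.0
        assert rayleigh_pdf(0.0, model_k8) == 0.0

    @pytest.mark.parametrize("coils", [1, 2, 4, 8])
    @pytest.mark.parametrize("sigma", [0.5, 2.05, 10.0])
    def test_matches_explicit_formula(self, sigma, coils):
        m = np.linspace(0.0, 30 * sigma, 400)
        model = NoiseModel(sigma=sigma, coils=coils)
        np.testing.assert_allclose(
            rayleigh_pdf(m, model), explicit_pdf(m, sigma, coils), rtol=1e-10, atol=1e-300
        )

    def test_k1_reduces_to_classical_rayleigh(self):
        sigma = 2.05
        m = np.linspace(0.0, 25.0, 500)
        classical = np.where(m > 0, m / sigma**2 * np.exp(-(m**2) / (2 * sigma**2)), 0.0)
        np.testing.assert_allclose(
            rayleigh_pdf(m, NoiseModel(sigma, 1)), classical, rtol=1e-12, atol=1e-300
        )

    @pytest.mark.parametrize("coils", [1, 2, 4, 8])
    @pytest.mark.parametrize("sigma", [0.5, 2.05, 10.0])
    def test_normalization_and_mode(self, sigma, coils):
        model = NoiseModel(sigma=sigma, coils=coils)
        total, _ = integrate.quad(lambda m: rayleigh_pdf(m, model), 0, 40 * sigma)
        assert total == pytest.approx(1.0, abs=1e-6)
        # dense grid argmax vs closed-form mode sigma*sqrt(2K-1)
        grid = np.linspace(0, 10 * sigma * math.sqrt(coils), 200001)
        argmax = grid[np.argmax(rayleigh_pdf(grid, model))]
        assert argmax == pytest.approx(sigma * math.sqrt(2 * coils - 1), abs=grid[1] * 2)

    def test_invalid_model_rejected(self):
        with pytest.raises(ParameterError):
            NoiseModel(sigma=0.0, coils=8)
        with pytest.raises(ParameterError):
            NoiseModel(sigma=2.05, coils=0)


class TestRayleighCdf:
    def test_zero_at_origin_monotone_to_one(self, model_k8):
        assert rayleigh_cdf(0.0, model_k8) == 0.0
        assert rayleigh_cdf(-3.0, model_k8) == 0.0
        m = np.linspace(0, 60, 500)
        c = rayleigh_cdf(m, model_k8)
        assert np.all(np.diff(c) >= 0)
        assert rayleigh_cdf(200.0, model_k8) == pytest.approx(1.0, abs=1e-12)

    def test_median_by_bisection(self, model_k8):
        lo, hi = 0.0, 100.0
        for _ in range(100):
            mid = (lo + hi) / 2
            if rayleigh_cdf(mid, model_k8) < 0.5:
                lo = mid
            else:
                hi = mid
        assert rayleigh_cdf((lo + hi) / 2, model_k8) == pytest.approx(0.5, abs=1e-9)

    def test_consistent_with_pdf_quadrature(self, model_k8):
        mode = model_k8.mode
        oracle, _ = integrate.quad(lambda m: rayleigh_pdf(m, model_k8), 0, mode)
        assert rayleigh_cdf(mode, model_k8) == pytest.approx(oracle, abs=1e-9)


class TestRcThreshold:
    def test_vanishes_for_degenerate_noise(self):
        assert rc_threshold(NoiseModel(sigma=1e-9, coils=8)) <= 1

    def test_shifts_higher_with_noisier_background(self):
        # doubling the background SD must raise the cutoff
        assert rc_threshold(NoiseModel(4.10, 8)) > rc_threshold(NoiseModel(2.05, 8))

    def test_monotone_in_sigma_and_tail_mass(self):
        sigmas = [0.5, 1.0, 2.05, 4.1, 8.2]
        thr = [rc_threshold(NoiseModel(s, 8)) for s in sigmas]
        assert all(b >= a for a, b in zip(thr, thr[1:]))
        quants = [rc_quantile(NoiseModel(s, 8)) for s in sigmas]
        assert all(b > a for a, b in zip(quants, quants[1:]))
        assert rc_threshold(NoiseModel(2.05, 8), tail_mass=1e-6) >= rc_threshold(
            NoiseModel(2.05, 8), tail_mass=1e-2
        )

    def test_matches_bisection_on_quadrature_cdf_oracle(self, model_k8):
        tail = 1e-4
        target = 1.0 - tail

        def cdf_oracle(x):
            val, _ = integrate.quad(lambda m: explicit_pdf(m, 2.05, 8), 0, x)
            return val

        lo, hi = 0.0, 100.0
        for _ in range(60):
            mid = (lo + hi) / 2
            if cdf_oracle(mid) < target:
                lo = mid
            else:
                hi = mid
        assert rc_threshold(model_k8, tail) == math.ceil(hi)

    def test_saturated_noise_rejected(self):
        with pytest.raises(SaturatedNoiseError):
            rc_threshold(NoiseModel(sigma=60.0, coils=8))

    def test_invalid_tail_mass(self, model_k8):
        with pytest.raises(ParameterError):
            rc_threshold(model_k8, tail_mass=0.7)


class TestEstimateSigma:
    def test_constant_roi_is_degenerate(self):
        with pytest.raises(DegenerateBackgroundError):
            estimate_sigma([3, 3, 3, 3])

    def test_moment_corrected_recovers_generating_sigma(self, rng):
        mags = sos_magnitude(rng, sigma_channel=2.0, coils=8, n=100_000)
        est = estimate_sigma(mags, method="moment_corrected", coils=8)
        assert est == pytest.approx(2.0, rel=0.02)

    def test_direct_returns_sample_sd_scaled_by_chi_factor(self, rng):
        mags = sos_magnitude(rng, sigma_channel=2.0, coils=8, n=100_000)
        direct = estimate_sigma(mags, method="direct")
        # closed-form chi variance: SD of the magnitude is sigma*sqrt(2K - c^2)
        assert direct == pytest.approx(2.0 * chi_sd_factor(8), rel=0.02)
        assert direct == pytest.approx(
            estimate_sigma(mags, method="moment_corrected", coils=8) * chi_sd_factor(8),
            rel=1e-12,
        )

    def test_chi_moment_factors_closed_form(self):
        # K=1: classical Rayleigh mean sqrt(pi/2), var 2 - pi/2
        assert chi_mean_factor(1) == pytest.approx(math.sqrt(math.pi / 2), rel=1e-12)
        assert chi_sd_factor(1) == pytest.approx(math.sqrt(2 - math.pi / 2), rel=1e-12)


def _hist_from_counts(counts):
    counts = np.asarray(counts, dtype=float)
    return IntensityHistogram(bins=100.0 * counts / counts.sum(), n_pixels=int(counts.sum()))


class TestGaussianFit:
    def test_self_fit_of_discretized_gaussian(self):
        x = np.arange(256, dtype=float)
        bins = np.exp(-0.5 * ((x - 40.0) / 6.0) ** 2)
        hist = IntensityHistogram(bins=100 * bins / bins.sum(), n_pixels=10_000)
        fit = fit_gaussian_to_histogram(hist)
        assert fit.fitting_error_percent < 0.5
        assert fit.mean == pytest.approx(40.0, abs=0.1)
        assert fit.sd == pytest.approx(6.0, abs=0.1)

    def test_fit_of_sampled_noise_histogram(self, model_k8, rng):
        draws = np.round(model_k8.dist.rvs(size=100_000, random_state=rng)).astype(int)
        hist = _hist_from_counts(np.bincount(np.clip(draws, 0, 255), minlength=256))
        fit = fit_gaussian_to_histogram(hist)
        assert fit.fitting_error_percent > 0
        assert fit.mean == pytest.approx(model_k8.mean, abs=0.5)

    def test_too_few_bins_rejected(self):
        counts = np.zeros(256)
        counts[[10, 20]] = 50
        with pytest.raises(InsufficientDataError):
            fit_gaussian_to_histogram(_hist_from_counts(counts))


class TestGaussianVsMeasured:
    def test_identical_curves_give_zero_t(self):
        x = np.arange(256, dtype=float)
        bins = np.exp(-0.5 * ((x - 30.0) / 5.0) ** 2)
        hist = IntensityHistogram(bins=100 * bins / bins.sum(), n_pixels=1000)
        fit = fit_gaussian_to_histogram(hist)
        object.__setattr__(fit, "fitted_bins", hist.bins.copy())
        t, p = gaussian_vs_measured_test(hist, fit)
        assert t == 0.0 and p == 1.0

    def test_antisymmetry(self, rng):
        from lgequant.noise import GaussianFit

        counts_a = np.zeros(256)
        counts_a[5:25] = rng.integers(1, 50, size=20)
        hist_a = _hist_from_counts(counts_a)
        counts_b = np.zeros(256)
        counts_b[10:30] = rng.integers(1, 50, size=20)
        hist_b = _hist_from_counts(counts_b)

        def fake_fit(curve):
            return GaussianFit(mean=0, sd=1, amplitude=0,
                               fitting_error_percent=0, fitted_bins=curve)

        t_ab, p_ab = gaussian_vs_measured_test(hist_a, fake_fit(hist_b.bins))
        t_ba, p_ba = gaussian_vs_measured_test(hist_b, fake_fit(hist_a.bins))
        assert t_ba == pytest.approx(-t_ab, rel=1e-12)
        assert p_ba == pytest.approx(p_ab, rel=1e-12)

    def test_constant_offset_is_degenerate(self):
        x = np.arange(256, dtype=float)
        bins = np.zeros(256)
        bins[10:20] = 10.0
        hist = IntensityHistogram(bins=bins, n_pixels=100)
        fit = fit_gaussian_to_histogram(
            IntensityHistogram(bins=bins, n_pixels=100)
        )
        shifted = np.where(bins > 0, bins - 1.0, 0.0)
        object.__setattr__(fit, "fitted_bins", shifted)
        with pytest.raises(DegenerateDifferenceError):
            gaussian_vs_measured_test(hist, fit)

    def test_significant_difference_from_noise_shape(self, model_k8, rng):
        # a non-Gaussian (chi) histogram should differ measurably from its
        # best Gaussian fit at large n
        draws = np.round(model_k8.dist.rvs(size=200_000, random_state=rng)).astype(int)
        hist = _hist_from_counts(np.bincount(np.clip(draws, 0, 255), minlength=256))
        fit = fit_gaussian_to_histogram(hist)
        t, p = gaussian_vs_measured_test(hist, fit)
        assert np.isfinite(t) and 0 <= p <= 1
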