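"""Noise model for sum-of-squares multi-coil magnitude MR images.

When normal myocardium is perfectly nulled by the inversion time, the
magnitude signal reconstructed as the root-sum-of-squares of ``K``
phased-array channels contains noise only.  Its probability density is a
generalized Rayleigh distribution — a chi distribution with ``2K`` degrees
of freedom scaled by the per-channel noise level ``sigma``:

    p(m) = m^(2K-1) / (2^(K-1) sigma^(2K) (K-1)!) * exp(-m^2 / (2 sigma^2)),  m >= 0

For ``K = 1`` this reduces to the classical Rayleigh density.  The model
supplies the "Rayleigh curve" used as the ideal intensity distribution of
nulled myocardium, the RC enhancement cutoff (the practical maximum of that
curve), sigma estimation from a background ROI, and a Gaussian-approximation
comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
from scipy import optimize, stats

from .errors import (
    DegenerateBackgroundError,
    DegenerateDifferenceError,
    FitFailureError,
    InsufficientDataError,
    ParameterError,
    SaturatedNoiseError,
)

if TYPE_CHECKING:  # pragma: no cover
    from .histogram import IntensityHistogram

__all__ = [
    "NoiseModel",
    "GaussianFit",
    "rayleigh_pdf",
    "rayleigh_cdf",
    "rc_threshold",
    "estimate_sigma",
    "chi_sd_factor",
    "chi_mean_factor",
    "fit_gaussian_to_histogram",
    "gaussian_vs_measured_test",
]


def chi_mean_factor(coils: int) -> float:
    """Mean of a unit-scale chi variate with ``2*coils`` degrees of freedom.

    c = sqrt(2) * Gamma(K + 1/2) / Gamma(K); the magnitude mean is ``c * sigma``.
    """
    k = float(coils)
    return math.sqrt(2.0) * math.exp(math.lgamma(k + 0.5) - math.lgamma(k))


def chi_sd_factor(coils: int) -> float:
    """SD of a unit-scale chi variate with ``2*coils`` degrees of freedom.

    sqrt(2K - c^2); the magnitude SD is this factor times ``sigma``, so the
    raw SD of a background ROI *under*-estimates the chi scale parameter.
    """
    c = chi_mean_factor(coils)
    return math.sqrt(2.0 * coils - c * c)


@dataclass(frozen=True)
class NoiseModel:
    """Generalized Rayleigh (chi, 2K dof) noise model of nulled myocardium.

    Parameters
    ----------
    sigma : float
        Scale parameter in 8-bit intensity units. Positive.
    coils : int, default 8
        Number of phased-array elements K combined by root-sum-of-squares.
    """

    sigma: float
    coils: int = 8

    def __post_init__(self) -> None:
        if not np.isfinite(self.sigma) or self.sigma <= 0:
            raise ParameterError(f"sigma must be a positive finite number, got {self.sigma}")
        if int(self.coils) != self.coils or self.coils < 1:
            raise ParameterError(f"coils must be an integer >= 1, got {self.coils}")

    @property
    def dist(self) -> stats.rv_continuous:
        """The scipy frozen chi distribution with 2K dof and scale sigma."""
        return stats.chi(2 * self.coils, scale=self.sigma)

    @property
    def mode(self) -> float:
        """Closed-form mode of the density: sigma * sqrt(2K - 1)."""
        return self.sigma * math.sqrt(2 * self.coils - 1)

    @property
    def mean(self) -> float:
        return chi_mean_factor(self.coils) * self.sigma

    @property
    def sd(self) -> float:
        return chi_sd_factor(self.coils) * self.sigma


def rayleigh_pdf(m, model: NoiseModel):
    """Density of the noise-only magnitude signal at intensity ``m``.

    Zero for negative ``m`` (the unit step in the model definition).
    Accepts scalars or arrays.
    """
    m = np.asarray(m, dtype=float)
    out = np.zeros_like(m)
    pos = m > 0
    out[pos] = model.dist.pdf(m[pos])
    return out if out.ndim else float(out)


def rayleigh_cdf(m, model: NoiseModel):
    """Cumulative probability of the noise-only magnitude at intensity ``m``."""
    m = np.asarray(m, dtype=float)
    out = np.zeros_like(m)
    pos = m > 0
    out[pos] = model.dist.cdf(m[pos])
    return out if out.ndim else float(out)


def rc_quantile(model: NoiseModel, tail_mass: float = 1e-4) -> float:
    """Continuous (1 - tail_mass) quantile of the noise model.

    Strictly increasing in sigma at fixed coils and tail mass; the integer
    RC cutoff is this value rounded up.
    """
    if not 0 < tail_mass < 0.5:
        raise ParameterError(f"tail_mass must be in (0, 0.5), got {tail_mass}")
    return float(model.dist.ppf(1.0 - tail_mass))


def rc_threshold(model: NoiseModel, tail_mass: float = 1e-4) -> int:
    """RC enhancement cutoff: practical maximum of the Rayleigh curve.

    The density has unbounded support, so the "maximal measurable" intensity
    is operationalized as the smallest intensity with upper-tail mass at most
    ``tail_mass``, rounded up to the next integer bin of the 0-255 scale.

    Raises
    ------
    SaturatedNoiseError
        If the cutoff exceeds 255 (noise fills the 8-bit range).
    """
    t = int(math.ceil(rc_quantile(model, tail_mass)))
    if t > 255:
        raise SaturatedNoiseError(
            f"RC threshold {t} exceeds the 8-bit range for sigma={model.sigma}"
        )
    return t


def estimate_sigma(
    background_pixels,
    method: str = "direct",
    coils: int = 8,
) -> float:
    """Estimate the noise parameter sigma from background-ROI intensities.

    method="direct"
        Sample SD of the ROI, used verbatim as sigma (the field convention:
        "the SD measured in the background").
    method="moment_corrected"
        Sample SD divided by sqrt(2K - c^2), the chi SD-to-scale factor, which
        recovers the true chi scale (= per-channel SD) for ideal
        sum-of-squares noise.

    Raises
    ------
    DegenerateBackgroundError
        If the ROI is constant-valued (SD = 0).
    """
    px = np.asarray(background_pixels, dtype=float).ravel()
    if px.size < 2:
        raise InsufficientDataError("sigma estimation needs at least 2 background pixels")
    if np.any(px < 0):
        raise ParameterError("magnitude intensities must be nonnegative")
    sd = float(np.std(px, ddof=1))
    if sd == 0.0:
        raise DegenerateBackgroundError("constant-valued background ROI; cannot estimate sigma")
    if method == "direct":
        return sd
    if method == "moment_corrected":
        return sd / chi_sd_factor(coils)
    raise ParameterError(f"unknown sigma estimation method: {method!r}")


@dataclass(frozen=True)
class GaussianFit:
    """Result of a least-squares Gaussian fit to an intensity histogram."""

    mean: float
    sd: float
    amplitude: float
    fitting_error_percent: float
    fitted_bins: np.ndarray = field(repr=False)

    def astuple(self) -> tuple[float, float, float]:
        return (self.mean, self.sd, self.fitting_error_percent)


def _gauss(x, amplitude, mean, sd):
    return amplitude * np.exp(-0.5 * ((x - mean) / sd) ** 2)


def fit_gaussian_to_histogram(hist: "IntensityHistogram", max_iter: int = 200) -> GaussianFit:
    """Fit a scaled Gaussian to a 256-bin percentage histogram.

    Uses Levenberg-Marquardt nonlinear least squares, initialized at the
    histogram moments.  The fitting error is the normalized L1 residual,
    sum|measured - fitted| / sum(measured) * 100, a scale-free percentage.

    Raises
    ------
    InsufficientDataError
        Fewer than 3 nonzero bins.
    FitFailureError
        Non-convergence within ``max_iter`` iterations.
    """
    bins = np.asarray(hist.bins, dtype=float)
    x = np.arange(bins.size, dtype=float)
    if int(np.count_nonzero(bins)) < 3:
        raise InsufficientDataError("Gaussian fit needs at least 3 nonzero histogram bins")
    total = bins.sum()
    mu0 = float((x * bins).sum() / total)
    var0 = float(((x - mu0) ** 2 * bins).sum() / total)
    sd0 = max(math.sqrt(max(var0, 0.0)), 0.5)
    a0 = float(bins.max())
    try:
        popt, _ = optimize.curve_fit(
            _gauss, x, bins, p0=(a0, mu0, sd0), method="lm", maxfev=max_iter * 4
        )
    except RuntimeError as exc:
        resid = float(np.abs(bins - _gauss(x, a0, mu0, sd0)).sum())
        raise FitFailureError(f"Gaussian fit did not converge: {exc}", last_residual=resid)
    amplitude, mean, sd = float(popt[0]), float(popt[1]), abs(float(popt[2]))
    fitted = _gauss(x, amplitude, mean, sd)
    err = float(np.abs(bins - fitted).sum() / total * 100.0)
    return GaussianFit(mean=mean, sd=sd, amplitude=amplitude,
                       fitting_error_percent=err, fitted_bins=fitted)


def gaussian_vs_measured_test(
    hist: "IntensityHistogram", fit: GaussianFit
) -> tuple[float, float]:
    """Bin-paired t test between the measured histogram and its Gaussian fit.

    Differences are taken bin-wise over the union support (bins where either
    curve is materially nonzero).  Antisymmetric: swapping the two curves
    negates t.

    Raises
    ------
    InsufficientDataError
        Fewer than 3 support bins.
    DegenerateDifferenceError
        Constant nonzero difference (zero variance, t undefined).
    """
    measured = np.asarray(hist.bins, dtype=float)
    fitted = np.asarray(fit.fitted_bins, dtype=float)
    support = (measured > 0) | (fitted > 1e-12)
    n = int(support.sum())
    if n < 3:
        raise InsufficientDataError("t test needs at least 3 support bins")
    diffs = measured[support] - fitted[support]
    sd = float(np.std(diffs, ddof=1))
    if sd == 0.0:
        if float(np.abs(diffs).max()) == 0.0:
            return 0.0, 1.0
        raise DegenerateDifferenceError(
            "constant nonzero difference between curves; paired t undefined"
        )
    res = stats.ttest_1samp(diffs, 0.0)
    return float(res.statistic), float(res.pvalue)
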