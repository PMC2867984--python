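"""Myocardial intensity histograms and the histogram-concordance statistic.

The measured distribution of 8-bit myocardial signal is compared against the
ideal "Rayleigh curve" of perfectly nulled myocardium (the noise model
discretized onto the same 0-255 integer grid).  Concordance is the area of
the bin-wise intersection of the two curves as a percentage of the area under
the reference curve: near 100% for normal myocardium, reduced when
enhancement shifts myocardial signal to higher intensities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import MaskError, ModelError, ParameterError
from .image import GrayImage
from .noise import NoiseModel, rc_threshold

__all__ = [
    "IntensityHistogram",
    "myocardial_histogram",
    "discretized_rayleigh_curve",
    "concordance",
]

N_BINS = 256


@dataclass(frozen=True)
class IntensityHistogram:
    """Percent of pixels at each integer intensity 0-255."""

    bins: np.ndarray
    n_pixels: int

    def __post_init__(self) -> None:
        bins = np.asarray(self.bins, dtype=float)
        if bins.shape != (N_BINS,):
            raise ParameterError(f"histogram must have {N_BINS} bins, got {bins.shape}")
        if np.any(bins < 0):
            raise ParameterError("histogram bins must be nonnegative")
        if abs(bins.sum() - 100.0) > 1e-9:
            raise ParameterError(f"histogram bins must sum to 100, got {bins.sum()}")
        if self.n_pixels < 1:
            raise ParameterError("histogram requires at least one pixel")
        object.__setattr__(self, "bins", bins)

    def to_csv(self, path) -> None:
        """Write as 2-column CSV (intensity, percent)."""
        arr = np.column_stack([np.arange(N_BINS), self.bins])
        np.savetxt(path, arr, fmt=["%d", "%.10g"], delimiter=",",
                   header="intensity,percent", comments="")


def myocardial_histogram(image8: GrayImage, mask) -> IntensityHistogram:
    """Distribution of 8-bit signal over the masked myocardium, in percent."""
    if image8.bit_depth != "8bit":
        raise ParameterError("histogramming requires an 8-bit image")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image8.shape:
        raise MaskError("mask must be congruent with the image")
    vals = image8.pixels[mask]
    if vals.size == 0:
        raise MaskError("mask selects no pixels")
    counts = np.bincount(vals.astype(np.int64).ravel(), minlength=N_BINS)
    return IntensityHistogram(bins=100.0 * counts / vals.size, n_pixels=int(vals.size))


def discretized_rayleigh_curve(model: NoiseModel, tail_mass: float = 1e-4) -> np.ndarray:
    """The noise model integrated per integer bin, as percentages.

    Bin i carries 100x the model probability mass on [i - 0.5, i + 0.5),
    clipped to [0, inf) — the distribution an 8-bit histogram of pure noise
    converges to.  Sums to 100 * CDF(255.5), i.e. essentially 100 for any
    realistic sigma; a model whose RC cutoff leaves the 8-bit range raises
    a saturation error.
    """
    rc_threshold(model, tail_mass)  # raises SaturatedNoiseError if off-scale
    edges = np.clip(np.arange(N_BINS + 1) - 0.5, 0.0, None)
    cdf = model.dist.cdf(edges)
    return 100.0 * np.diff(cdf)


def concordance(measured, reference) -> float:
    """Intersection area of two intensity curves, in percent of the reference.

    100 * sum_i min(measured_i, reference_i) / sum_i reference_i, evaluated
    bin-wise on the 0-255 integer grid.  Identical curves score 100; curves
    with disjoint support score 0.
    """
    m = measured.bins if isinstance(measured, IntensityHistogram) else np.asarray(measured, float)
    r = reference.bins if isinstance(reference, IntensityHistogram) else np.asarray(reference, float)
    if m.shape != (N_BINS,) or r.shape != (N_BINS,):
        raise ParameterError("both curves must live on the 0-255 integer grid")
    denom = float(r.sum())
    if denom <= 0:
        raise ModelError("reference curve has zero area")
    return 100.0 * float(np.minimum(m, r).sum()) / denom
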