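"""Synthetic K-coil magnitude MR phantoms with known ground truth.

Each phantom emulates one short-axis inversion-recovery slice: a bright
left-ventricular blood pool, a nulled myocardial annulus whose signal is
pure noise (plus optional residual nulling error), optional enhanced
lesions, air background, and exact-zero padding outside the inscribed
reconstruction circle.  Pixels are generated per coil channel as complex
Gaussian noise around the true amplitude and combined by root-sum-of-squares,
so noise-only regions follow the chi distribution with 2K degrees of freedom
that the analysis assumes.

Amplitudes are expressed in multiples of the chi-scale sigma (the
per-channel noise SD); the per-channel SD itself is calibrated so that the
*magnitude* SD of the background equals ``PhantomSpec.sigma``, keeping the
"SD measured in the background ROI" the ground-truth quantity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import PhantomSpecError
from .image import BoxROI, GrayImage, SegmentationSet
from .noise import chi_sd_factor

__all__ = [
    "DiscLesion",
    "WedgeLesion",
    "PhantomSpec",
    "Subject",
    "simulate_image",
    "simulate_cohort",
]


@dataclass(frozen=True)
class DiscLesion:
    """Circular lesion: center in mm (image coordinates), radius in mm,
    amplitude in multiples of the chi-scale sigma."""

    center_mm: tuple[float, float]
    radius_mm: float
    amplitude: float


@dataclass(frozen=True)
class WedgeLesion:
    """Angular sector of the myocardial annulus between two angles (radians,
    mathematical convention), amplitude in multiples of the chi-scale sigma."""

    theta_start: float
    theta_end: float
    amplitude: float


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and signal model of one synthetic short-axis slice.

    Defaults follow the study acquisition: 256 x 256 reconstruction over a
    400 mm field of view (1.5625 mm/pixel), K = 8 coils, background
    magnitude SD 2.05, a hypertrophic-thickness annulus, and a blood pool
    bright enough to pin the display window (so the 8-bit background SD
    stays near 2).
    """

    image_shape: tuple[int, int] = (256, 256)
    pixel_spacing_mm: tuple[float, float] = (1.5625, 1.5625)
    sigma: float = 2.05  # target background *magnitude* SD, raw units
    coils: int = 8
    center_mm: tuple[float, float] | None = None  # defaults to image center
    endo_radius_mm: float = 22.0
    epi_radius_mm: float = 40.0
    lesions: tuple = ()
    myo_true_signal: float = 0.0  # residual nulling error, multiples of chi-scale sigma
    blood_signal: float = 85.0  # blood-pool amplitude, multiples of chi-scale sigma
    background_roi_side_mm: float = 25.0
    zero_pad_outside_fov: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise PhantomSpecError("sigma must be positive")
        if self.coils < 1:
            raise PhantomSpecError("coils must be >= 1")
        if not self.endo_radius_mm < self.epi_radius_mm:
            raise PhantomSpecError("endocardial radius must be smaller than epicardial radius")
        if self.myo_true_signal < 0 or self.blood_signal < 0:
            raise PhantomSpecError("amplitudes must be nonnegative")
        for les in self.lesions:
            if les.amplitude < 0:
                raise PhantomSpecError("lesion amplitudes must be nonnegative")

    @property
    def chi_scale_sigma(self) -> float:
        """Per-channel noise SD: sigma / sqrt(2K - c^2)."""
        return self.sigma / chi_sd_factor(self.coils)

    @property
    def center_px(self) -> tuple[float, float]:
        if self.center_mm is not None:
            return (
                self.center_mm[0] / self.pixel_spacing_mm[0],
                self.center_mm[1] / self.pixel_spacing_mm[1],
            )
        return ((self.image_shape[0] - 1) / 2.0, (self.image_shape[1] - 1) / 2.0)


def _grid_mm(spec: PhantomSpec):
    rows = np.arange(spec.image_shape[0])[:, None] * spec.pixel_spacing_mm[0]
    cols = np.arange(spec.image_shape[1])[None, :] * spec.pixel_spacing_mm[1]
    cr, cc = spec.center_px
    dr = rows - cr * spec.pixel_spacing_mm[0]
    dc = cols - cc * spec.pixel_spacing_mm[1]
    return dr, dc


def _annulus_masks(spec: PhantomSpec):
    dr, dc = _grid_mm(spec)
    r = np.hypot(dr, dc)
    endo = r <= spec.endo_radius_mm
    epi = r <= spec.epi_radius_mm
    return endo, epi, r


def _lesion_mask(spec: PhantomSpec, lesion, annulus: np.ndarray) -> np.ndarray:
    dr, dc = _grid_mm(spec)
    if isinstance(lesion, DiscLesion):
        rows = np.arange(spec.image_shape[0])[:, None] * spec.pixel_spacing_mm[0]
        cols = np.arange(spec.image_shape[1])[None, :] * spec.pixel_spacing_mm[1]
        d = np.hypot(rows - lesion.center_mm[0], cols - lesion.center_mm[1])
        mask = d <= lesion.radius_mm
    elif isinstance(lesion, WedgeLesion):
        theta = np.arctan2(-dr, dc)  # mathematical angle, row axis points down
        span = (lesion.theta_end - lesion.theta_start) % (2 * math.pi)
        rel = (theta - lesion.theta_start) % (2 * math.pi)
        mask = annulus & (rel <= span)
    else:  # pragma: no cover
        raise PhantomSpecError(f"unknown lesion type {type(lesion).__name__}")
    if np.any(mask & ~annulus):
        raise PhantomSpecError("lesion extends outside the myocardial annulus")
    if not mask.any():
        raise PhantomSpecError("lesion covers no pixels")
    return mask


def _background_roi(spec: PhantomSpec, epi: np.ndarray, truth: np.ndarray) -> BoxROI:
    """Square noise-only ROI inside the reconstruction circle, clear of the LV.

    Placed against the mid-left edge (the air gap near the thoracic wall),
    falling back to the other edge midpoints if occupied.
    """
    side = (
        int(round(spec.background_roi_side_mm / spec.pixel_spacing_mm[0])),
        int(round(spec.background_roi_side_mm / spec.pixel_spacing_mm[1])),
    )
    h, w = spec.image_shape
    inside_fov = _fov_mask(spec)
    for margin in (2, 4, 8, 12, 16, 24, 32, 48, 64):
        anchors = [
            ((h - side[0]) // 2, margin),
            ((h - side[0]) // 2, w - side[1] - margin),
            (margin, (w - side[1]) // 2),
            (h - side[0] - margin, (w - side[1]) // 2),
        ]
        for r, c in anchors:
            if r < 0 or c < 0 or r + side[0] > h or c + side[1] > w:
                continue
            box = np.zeros(spec.image_shape, dtype=bool)
            box[r : r + side[0], c : c + side[1]] = True
            if not np.any(box & (epi | truth)) and np.all(inside_fov[box]):
                return BoxROI(row=r, col=c, side_mm=spec.background_roi_side_mm)
    raise PhantomSpecError("no lesion-free background ROI placement found")


def _fov_mask(spec: PhantomSpec) -> np.ndarray:
    if not spec.zero_pad_outside_fov:
        return np.ones(spec.image_shape, dtype=bool)
    h, w = spec.image_shape
    dr = np.arange(h)[:, None] - (h - 1) / 2.0
    dc = np.arange(w)[None, :] - (w - 1) / 2.0
    return np.hypot(dr, dc) <= min(h, w) / 2.0


def simulate_image(
    spec: PhantomSpec, rng: np.random.Generator | None = None
) -> tuple[GrayImage, SegmentationSet, np.ndarray]:
    """Generate one raw magnitude slice plus segmentation and ground truth.

    Returns (raw GrayImage, SegmentationSet, true enhanced mask).  The
    amplitude map is split evenly across the K complex channels, each
    perturbed by independent Gaussian noise, and recombined by
    root-sum-of-squares, so every region follows the (non)central chi law
    of its true amplitude.  Fixed seed -> bit-identical output.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    endo, epi, _ = _annulus_masks(spec)
    annulus = epi & ~endo

    sigma_ch = spec.chi_scale_sigma
    amplitude = np.zeros(spec.image_shape, dtype=float)
    amplitude[endo] = spec.blood_signal * sigma_ch
    amplitude[annulus] = spec.myo_true_signal * sigma_ch

    truth = np.zeros(spec.image_shape, dtype=bool)
    for lesion in spec.lesions:
        mask = _lesion_mask(spec, lesion, annulus)
        amplitude[mask] = lesion.amplitude * sigma_ch
        if lesion.amplitude > 0:
            truth |= mask

    k = spec.coils
    per_channel = amplitude / math.sqrt(k)
    shape = (k, *spec.image_shape)
    re = per_channel[None, :, :] + rng.normal(0.0, sigma_ch, size=shape)
    im = rng.normal(0.0, sigma_ch, size=shape)
    magnitude = np.sqrt(np.sum(re * re + im * im, axis=0))

    fov = _fov_mask(spec)
    magnitude[~fov] = 0.0

    bg_roi = _background_roi(spec, epi, truth)
    normal_myo = annulus & ~truth
    seg = SegmentationSet(
        endo_mask=endo, epi_mask=epi, background_roi=bg_roi, myocardial_roi=normal_myo
    )
    img = GrayImage(pixels=magnitude, pixel_spacing_mm=spec.pixel_spacing_mm, bit_depth="raw")
    return img, seg, truth


@dataclass(frozen=True)
class Subject:
    """One simulated subject with full ground truth."""

    subject_id: str
    group: str  # "positive" / "negative"
    image_raw: GrayImage = field(repr=False)
    seg: SegmentationSet = field(repr=False)
    truth_mask: np.ndarray = field(repr=False)
    true_enhanced_fraction: float
    spec: PhantomSpec = field(repr=False)


def wedge_for_fraction(fraction: float, amplitude: float, theta_start: float = 0.0) -> WedgeLesion:
    """A wedge lesion covering the given fraction of the annulus."""
    if not 0 < fraction <= 1:
        raise PhantomSpecError("enhanced fraction must lie in (0, 1]")
    return WedgeLesion(
        theta_start=theta_start,
        theta_end=theta_start + fraction * 2 * math.pi,
        amplitude=amplitude,
    )


def simulate_cohort(
    n_positive: int,
    n_negative: int,
    enhancement_range: tuple[float, float] = (0.2, 0.4),
    contrast_range: tuple[float, float] = (8.0, 16.0),
    seed: int = 0,
    base_spec: PhantomSpec | None = None,
) -> list[Subject]:
    """Simulate a two-group study: lesioned positives and noise-only negatives.

    Positives carry a wedge lesion occupying a fraction of the annulus drawn
    uniformly from ``enhancement_range`` at a contrast (multiples of the
    chi-scale sigma) drawn from ``contrast_range``; negatives are noise-only.
    All randomness flows from ``seed``; identical seeds give identical
    cohorts including ground truth.
    """
    if n_positive < 1 or n_negative < 1:
        raise PhantomSpecError("cohort needs at least one subject per group")
    lo_f, hi_f = enhancement_range
    lo_c, hi_c = contrast_range
    if not (0 < lo_f <= hi_f <= 1) or not (0 <= lo_c <= hi_c):
        raise PhantomSpecError("empty or invalid enhancement/contrast range")
    if base_spec is None:
        base_spec = PhantomSpec()
    rng = np.random.default_rng(seed)
    subjects: list[Subject] = []
    for i in range(n_positive + n_negative):
        positive = i < n_positive
        if positive:
            frac = float(rng.uniform(lo_f, hi_f))
            contrast = float(rng.uniform(lo_c, hi_c))
            start = float(rng.uniform(0, 2 * math.pi))
            lesions = (wedge_for_fraction(frac, contrast, theta_start=start),)
        else:
            lesions = ()
        spec = replace(base_spec, lesions=lesions, seed=int(rng.integers(0, 2**31 - 1)))
        img, seg, truth = simulate_image(spec)
        annulus = seg.epi_mask & ~seg.endo_mask
        subjects.append(
            Subject(
                subject_id=f"{'hcm' if positive else 'ctl'}{i:03d}",
                group="positive" if positive else "negative",
                image_raw=img,
                seg=seg,
                truth_mask=truth,
                true_enhanced_fraction=float(truth.sum() / annulus.sum()),
                spec=spec,
            )
        )
    return subjects
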