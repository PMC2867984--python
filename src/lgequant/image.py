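"""Image containers, 8-bit windowing, mask geometry and nulling-quality ratios."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .errors import ContourError, DegenerateROIError, GeometryError, MaskError, ParameterError

__all__ = [
    "GrayImage",
    "BoxROI",
    "SegmentationSet",
    "to_8bit",
    "myocardium_mask",
    "box_to_roi_pixels",
    "roi_pixels",
    "cnr",
    "nulling_ratio",
]


@dataclass(frozen=True)
class GrayImage:
    """A 2-D magnitude MR image with physical pixel spacing.

    ``bit_depth`` is "raw" for scanner-scale intensities and "8bit" after
    min-to-max windowing; 8-bit images hold integers in [0, 255].
    """

    pixels: np.ndarray
    pixel_spacing_mm: tuple[float, float]
    bit_depth: str = "raw"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ParameterError("image must be a nonempty 2-D array")
        if np.any(np.asarray(px, dtype=float) < 0):
            raise ParameterError("magnitude images must be nonnegative")
        sp = self.pixel_spacing_mm
        if len(sp) != 2 or sp[0] <= 0 or sp[1] <= 0:
            raise ParameterError(f"pixel spacing must be two positive reals, got {sp}")
        if self.bit_depth not in ("raw", "8bit"):
            raise ParameterError(f"bit_depth must be 'raw' or '8bit', got {self.bit_depth!r}")
        if self.bit_depth == "8bit":
            if px.max() > 255 or not np.issubdtype(px.dtype, np.integer):
                raise ParameterError("8bit images must hold integers in [0, 255]")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class BoxROI:
    """Axis-aligned square ROI: top-left anchor in pixels, side in mm."""

    row: int
    col: int
    side_mm: float

    def side_px(self, pixel_spacing_mm: tuple[float, float]) -> tuple[int, int]:
        return (
            int(round(self.side_mm / pixel_spacing_mm[0])),
            int(round(self.side_mm / pixel_spacing_mm[1])),
        )

    def mask(self, image: "GrayImage") -> np.ndarray:
        h, w = self.side_px(image.pixel_spacing_mm)
        m = np.zeros(image.shape, dtype=bool)
        m[self.row : self.row + h, self.col : self.col + w] = True
        return m


@dataclass(frozen=True)
class SegmentationSet:
    """Manual contours and ROIs accompanying one short-axis slice.

    ``endo_mask``/``epi_mask`` are filled boolean masks of the endocardial and
    epicardial contours (endo strictly inside epi); ``background_roi`` is a
    square box in air outside the chest wall; ``myocardial_roi`` is the
    visually normal myocardium used by the nSD methods, as a boolean mask or
    a :class:`BoxROI`.
    """

    endo_mask: np.ndarray
    epi_mask: np.ndarray
    background_roi: BoxROI
    myocardial_roi: np.ndarray | BoxROI | None = None

    def __post_init__(self) -> None:
        endo = np.asarray(self.endo_mask, dtype=bool)
        epi = np.asarray(self.epi_mask, dtype=bool)
        if endo.shape != epi.shape:
            raise MaskError("endocardial and epicardial masks must share a shape")
        if np.any(endo & ~epi):
            raise ContourError("endocardial mask extends outside the epicardial contour")
        object.__setattr__(self, "endo_mask", endo)
        object.__setattr__(self, "epi_mask", epi)

    def validate_against(self, image: GrayImage) -> None:
        if self.epi_mask.shape != image.shape:
            raise MaskError("segmentation masks must be congruent with the image")
        bg = self.background_roi.mask(image)
        if np.any(bg & self.epi_mask):
            raise GeometryError("background ROI overlaps the epicardial contour")


def to_8bit(image: GrayImage) -> GrayImage:
    """Min-to-max windowing onto the fixed 0-255 grayscale.

    The image minimum maps to 0 and the maximum to 255 (affine, rounded
    half-up), so display-window differences between acquisitions are nulled.
    A constant image maps to all zeros with a warning.
    """
    px = np.asarray(image.pixels, dtype=float)
    lo, hi = float(px.min()), float(px.max())
    if hi == lo:
        warnings.warn("constant image: 8-bit conversion maps all pixels to 0", stacklevel=2)
        out = np.zeros_like(px, dtype=np.uint8)
    else:
        scaled = (px - lo) * (255.0 / (hi - lo))
        out = np.floor(scaled + 0.5).astype(np.uint8)  # round half-up
    return replace(image, pixels=out, bit_depth="8bit")


def myocardium_mask(seg: SegmentationSet) -> np.ndarray:
    """Left-ventricular myocardium: epicardial mask minus the endocardial cavity."""
    mask = seg.epi_mask & ~seg.endo_mask
    if not mask.any():
        raise ContourError("contours enclose no myocardium")
    return mask


def box_to_roi_pixels(image: GrayImage, side_mm: float, anchor: tuple[int, int]) -> np.ndarray:
    """Intensities inside a square ROI of physical side ``side_mm``.

    The side in pixels is round(side_mm / pixel_spacing) per axis; e.g. a
    25 mm box at 1.5625 mm/pixel covers 16 x 16 = 256 pixels.
    """
    box = BoxROI(row=int(anchor[0]), col=int(anchor[1]), side_mm=side_mm)
    return roi_pixels(image, box)


def roi_pixels(image: GrayImage, roi: BoxROI | np.ndarray) -> np.ndarray:
    """Flattened pixel intensities of a BoxROI or boolean-mask ROI."""
    if isinstance(roi, BoxROI):
        h, w = roi.side_px(image.pixel_spacing_mm)
        r, c = roi.row, roi.col
        if r < 0 or c < 0 or r + h > image.shape[0] or c + w > image.shape[1]:
            raise GeometryError(
                f"ROI box ({r},{c}) side {h}x{w}px exceeds image bounds {image.shape}"
            )
        return np.asarray(image.pixels[r : r + h, c : c + w]).ravel()
    mask = np.asarray(roi, dtype=bool)
    if mask.shape != image.shape:
        raise MaskError("ROI mask must be congruent with the image")
    if not mask.any():
        raise MaskError("ROI mask selects no pixels")
    return np.asarray(image.pixels[mask]).ravel()


def cnr(myo_pixels, bk_pixels) -> float:
    """Contrast-to-noise ratio between nulled myocardium and background.

    2 * (mean_myo - mean_bk) / (SD_myo + SD_bk); a nulling-quality check —
    near zero when myocardium and background share the same noise process.
    """
    myo = np.asarray(myo_pixels, dtype=float).ravel()
    bk = np.asarray(bk_pixels, dtype=float).ravel()
    if myo.size < 2 or bk.size < 2:
        raise DegenerateROIError("CNR needs at least 2 pixels in each ROI")
    sd_sum = float(np.std(myo, ddof=1) + np.std(bk, ddof=1))
    if sd_sum == 0.0:
        raise DegenerateROIError("both ROIs constant-valued; CNR undefined")
    return 2.0 * float(myo.mean() - bk.mean()) / sd_sum


def nulling_ratio(myo_pixels, bk_pixels) -> float:
    """Ratio of mean myocardial to mean background intensity.

    Tends to 1 for perfectly nulled myocardium, whose signal is the same
    noise process as the background.
    """
    myo = np.asarray(myo_pixels, dtype=float).ravel()
    bk = np.asarray(bk_pixels, dtype=float).ravel()
    if myo.size == 0 or bk.size == 0 or bk.mean() == 0:
        raise DegenerateROIError("nulling ratio needs nonempty ROIs with nonzero background mean")
    return float(myo.mean() / bk.mean())
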