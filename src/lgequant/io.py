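"""Readers and writers: DICOM / array images, PNG masks, CSV reports,
parametric-map PNGs, and the run configuration."""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image as PILImage

from .errors import LgeQuantError, MetadataError
from .image import BoxROI, GrayImage
from .quantify import PARAMETRIC_PALETTE

__all__ = [
    "read_image",
    "read_mask",
    "write_mask_png",
    "write_parametric_png",
    "RunConfig",
    "load_run_config",
]


def read_image(path, pixel_spacing_mm: tuple[float, float] | None = None) -> GrayImage:
    """Load a raw magnitude image from DICOM or a numpy ``.npy`` archive.

    DICOM: pixel spacing is taken from the PixelSpacing tag and rescale
    slope/intercept are applied; negative rescaled values are clamped to 0
    with a warning (magnitude images are nonnegative).  Arrays: spacing must
    come from a ``<stem>.yaml`` sidecar (key ``pixel_spacing_mm``) or the
    ``pixel_spacing_mm`` argument.
    """
    path = Path(path)
    if path.suffix.lower() in (".dcm", ".ima") or path.suffix == "":
        return _read_dicom(path)
    if path.suffix.lower() == ".npy":
        try:
            arr = np.load(path)
        except Exception as exc:  # unreadable file
            raise LgeQuantError(f"cannot read array image {path}: {exc}") from exc
        if pixel_spacing_mm is None:
            sidecar = path.with_suffix(".yaml")
            if not sidecar.exists():
                raise MetadataError(f"no pixel spacing: missing sidecar {sidecar}")
            meta = yaml.safe_load(sidecar.read_text())
            try:
                pixel_spacing_mm = tuple(float(v) for v in meta["pixel_spacing_mm"])
            except (KeyError, TypeError) as exc:
                raise MetadataError(f"sidecar {sidecar} lacks pixel_spacing_mm") from exc
        arr = _clamp_nonnegative(np.asarray(arr, dtype=float))
        return GrayImage(pixels=arr, pixel_spacing_mm=pixel_spacing_mm, bit_depth="raw")
    raise LgeQuantError(f"unsupported image format: {path}")


def _read_dicom(path: Path) -> GrayImage:
    import pydicom

    try:
        ds = pydicom.dcmread(path)
        arr = ds.pixel_array.astype(float)
    except Exception as exc:
        raise LgeQuantError(f"cannot read DICOM {path}: {exc}") from exc
    spacing = getattr(ds, "PixelSpacing", None)
    if spacing is None:
        raise MetadataError(f"DICOM {path} has no PixelSpacing tag")
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    arr = _clamp_nonnegative(arr * slope + intercept)
    return GrayImage(
        pixels=arr,
        pixel_spacing_mm=(float(spacing[0]), float(spacing[1])),
        bit_depth="raw",
    )


def _clamp_nonnegative(arr: np.ndarray) -> np.ndarray:
    if np.any(arr < 0):
        warnings.warn("negative intensities clamped to 0 (magnitude image)", stacklevel=3)
        arr = np.clip(arr, 0.0, None)
    return arr


def read_mask(path) -> np.ndarray:
    """Boolean mask from an 8-bit PNG (nonzero = inside) or a ``.npy`` array."""
    path = Path(path)
    if not path.exists():
        raise LgeQuantError(f"mask file not found: {path}")
    if path.suffix.lower() == ".npy":
        return np.asarray(np.load(path)).astype(bool)
    return np.asarray(PILImage.open(path).convert("L")) > 0


def write_mask_png(path, mask: np.ndarray) -> None:
    PILImage.fromarray((np.asarray(mask, dtype=bool) * 255).astype(np.uint8)).save(path)


def write_parametric_png(path, labels: np.ndarray) -> None:
    """Save a 3-class parametric map as an indexed-color PNG.

    Palette: 0 black (outside LV), 1 gray (normal myocardium), 2 pink
    (enhanced myocardium).
    """
    img = PILImage.fromarray(np.asarray(labels, dtype=np.uint8), mode="P")
    palette = [0] * 768
    for label, rgb in PARAMETRIC_PALETTE.items():
        palette[3 * label : 3 * label + 3] = rgb
    img.putpalette(palette)
    img.save(path)


@dataclasses.dataclass
class RunConfig:
    """Configuration of one quantification run (YAML-loadable)."""

    image: str
    endo_mask: str
    epi_mask: str
    myo_roi_mask: str | None = None
    background_roi: tuple[int, int, float] = (0, 0, 25.0)  # row, col, side_mm
    pixel_spacing_mm: tuple[float, float] | None = None
    methods: tuple[str, ...] = ("SD2", "SD6", "RC")
    coils: int = 8
    tail_mass: float = 1e-4
    sigma_method: str = "moment_corrected"
    aggregation: str = "pooled"  # or "per-slice-mean"
    out_dir: str = "lgequant_out"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.coils < 1:
            raise MetadataError("coils must be >= 1")
        if not 0 < self.tail_mass < 0.5:
            raise MetadataError("tail_mass must lie in (0, 0.5)")

    def background_box(self) -> BoxROI:
        r, c, side = self.background_roi
        return BoxROI(row=int(r), col=int(c), side_mm=float(side))


def load_run_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    kwargs = dict(raw)
    for key in ("background_roi", "pixel_spacing_mm", "methods"):
        if key in kwargs and kwargs[key] is not None:
            kwargs[key] = tuple(kwargs[key])
    return RunConfig(**kwargs)


def write_run_metadata(path, config: RunConfig, extra: dict | None = None) -> None:
    import lgequant

    meta = {
        "package_version": lgequant.__version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config": dataclasses.asdict(config),
    }
    if extra:
        meta.update(extra)
    Path(path).write_text(json.dumps(meta, indent=2, default=str))
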