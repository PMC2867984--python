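"""Exception hierarchy for the LGE quantification pipeline.

Every error raised by the package derives from :class:`LgeQuantError` so
callers can catch pipeline failures without masking programming errors.
"""


class LgeQuantError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(LgeQuantError, ValueError):
    """An invalid model or configuration parameter (sigma <= 0, coils < 1, ...)."""


class DegenerateBackgroundError(LgeQuantError, ValueError):
    """Background ROI with zero intensity spread; sigma cannot be estimated."""


class SaturatedNoiseError(LgeQuantError, ValueError):
    """Noise threshold exceeds the 8-bit intensity range."""


class FitFailureError(LgeQuantError, RuntimeError):
    """Nonlinear fit did not converge; carries the last residual."""

    def __init__(self, message: str, last_residual: float | None = None):
        super().__init__(message)
        self.last_residual = last_residual


class InsufficientDataError(LgeQuantError, ValueError):
    """Too few histogram bins / pixels for the requested operation."""


class DegenerateDifferenceError(LgeQuantError, ValueError):
    """Paired differences with zero variance but nonzero mean; t is undefined."""


class GeometryError(LgeQuantError, ValueError):
    """ROI box outside the image bounds or otherwise inconsistent geometry."""


class ContourError(LgeQuantError, ValueError):
    """Endocardial/epicardial contours that do not describe a valid annulus."""


class MaskError(LgeQuantError, ValueError):
    """Empty or shape-mismatched segmentation mask."""


class DegenerateROIError(LgeQuantError, ValueError):
    """ROI statistics degenerate for the requested ratio (zero spread)."""


class ModelError(LgeQuantError, ValueError):
    """Reference noise curve unusable (e.g. zero area)."""


class GroupingError(LgeQuantError, ValueError):
    """ROC input lacking one of the two subject groups."""


class PhantomSpecError(LgeQuantError, ValueError):
    """Inconsistent synthetic phantom specification."""


class MetadataError(LgeQuantError, ValueError):
    """Required image metadata (e.g. pixel spacing) missing."""


class StageError(LgeQuantError, RuntimeError):
    """A pipeline stage failed; carries the stage name for reporting."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
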