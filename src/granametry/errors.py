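"""Exception hierarchy for granametry.

All domain failures derive from :class:`GranametryError` so pipelines can
catch one base class, log the image, and continue with the rest of a cohort.
"""


class GranametryError(Exception):
    """Base class for all granametry failures."""


class ValidationError(GranametryError, ValueError):
    """Invalid geometry, configuration, or argument values."""


class ResolutionError(GranametryError):
    """Requested structure is too fine for the pixel size (< 2 px per repeat)."""


class CalibrationError(GranametryError):
    """No nm-per-pixel calibration could be attached to an image."""


class DetectionError(GranametryError):
    """No dominant periodic orientation / no measurable band found."""


class FitQualityError(GranametryError):
    """A model fit failed to converge or fell below the quality floor."""


class SegmentationError(GranametryError):
    """Intensity classes are not separable (degenerate histogram)."""


class ExtractionError(GranametryError):
    """Stripe borders could not be linked into usable polylines."""


class InsufficientDataError(GranametryError):
    """Too few stripes/troughs/values to produce the requested measurement."""


class BinningError(GranametryError):
    """Histogram has too few occupied bins for a distribution fit."""
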