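"""Named exception hierarchy.

Every malformed-input condition raises a distinct, named error so callers
(and the CLI) can report context instead of crashing on a stack trace.
"""


class MfiError(Exception):
    """Base class for all package errors."""


class DicomReadError(MfiError):
    """DICOM file missing, unreadable, multi-frame, color, or without pixel data."""


class ImageReadError(MfiError):
    """Non-DICOM image fixture unreadable or not single-channel grayscale."""


class PolygonError(MfiError):
    """Degenerate or self-intersecting ROI polygon, or vertices out of bounds."""


class EmptyMaskError(MfiError):
    """Rasterization produced no pixels, or a mask too small to quartile."""


class RoiSchemaError(MfiError):
    """ROI JSON document violates the interchange schema."""


class DuplicateKeyError(MfiError):
    """Measurement table contains a repeated (subject, level, side, quartile, rater, session) key."""


class TableFormatError(MfiError):
    """Measurement CSV malformed: wrong header, non-numeric MFI, bad enum value."""


class MissingRoiError(MfiError):
    """A required ROI (fat reference) is absent for a level."""


class NormalizationError(MfiError):
    """Fat-reference mean intensity is zero or below the guard epsilon."""


class InsufficientDataError(MfiError):
    """Too few units, raters, sessions or pairs for the requested statistic."""


class DegenerateDataError(MfiError):
    """All ratings identical: total variance is zero and the ICC is undefined."""


class DesignInfeasibleError(MfiError):
    """Sample-size computation diverged past the configured cap."""


class GeometryError(MfiError):
    """Phantom geometry invalid (overlapping compartments, out of grid)."""


class JitterError(MfiError):
    """Rater-jitter simulation could not produce a simple polygon within the retry budget."""
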