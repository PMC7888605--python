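"""Exception hierarchy for visparc.

All package-raised errors derive from :class:`VisparcError` so callers can
catch a single base class; subclasses mirror the failure modes of each
pipeline stage (validation, degenerate inputs, model capacity, I/O schema).
"""


class VisparcError(Exception):
    """Base class for all visparc errors."""


class ValidationError(VisparcError, ValueError):
    """An input object violates a documented invariant."""


class SizingError(ValidationError):
    """A raster is too small to host the requested geometry."""


class DegenerateSignalError(ValidationError):
    """A simulation would produce identically-zero responses."""


class DegenerateCovarianceError(ValidationError):
    """Covariance (or between-class scatter) has no usable structure."""


class AlignmentError(ValidationError):
    """Trial windows of one stimulus have inconsistent lengths."""


class LengthError(ValidationError):
    """A requested window exceeds the available recording length."""


class ClassSizeError(ValidationError):
    """A class has too few samples for the requested fit."""


class MissingClassError(ValidationError):
    """An expected area code is absent from the training labels."""


class CapacityError(ValidationError):
    """Model capacity (e.g. mixture count) exceeds the available samples."""


class RadiusError(ValidationError):
    """Radius-restricted sampling left an area with no eligible pixels."""


class SchemaError(VisparcError):
    """An on-disk container does not match the expected layout."""
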