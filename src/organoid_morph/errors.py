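"""Exception hierarchy for the organoid-morph pipeline."""


class OrganoidMorphError(Exception):
    """Base class for all package errors."""


class ValidationError(OrganoidMorphError):
    """An input violates a documented precondition."""


class SchemaError(ValidationError):
    """A tabular input is missing required columns."""


class ManifestParseError(ValidationError):
    """A manifest row could not be parsed; carries the offending row number."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class UnsupportedFormatError(OrganoidMorphError):
    """The image file decodes but is not a supported single-frame raster."""


class ImageReadError(OrganoidMorphError):
    """The image file could not be read at all."""


class NoOrganoidFoundError(OrganoidMorphError):
    """Every segment was classified as background (empty or overexposed frame)."""


class BorderContactError(ValidationError):
    """The organoid mask touches the image border; the perimeter would be
    undefined along the cut. Pad the image and re-measure."""


class UndefinedFoldError(ValidationError):
    """Fold change is undefined because the baseline mean is zero."""


class ConfigError(ValidationError):
    """A configuration file contains unknown or invalid keys."""
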