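"""Exceptions shared across the package."""


class AsaqError(Exception):
    """Base class for package errors."""


class AlignmentFormatError(AsaqError):
    """Raised when an alignment file cannot be parsed or is malformed."""


class DegenerateDataError(AsaqError):
    """Raised when no usable alignment columns remain for a quartet."""


class UndefinedDistanceError(AsaqError):
    """Raised when a required paralinear distance is undefined."""


class MissingWeightError(AsaqError):
    """Raised when a quartet needed during tree building is absent from the table."""
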