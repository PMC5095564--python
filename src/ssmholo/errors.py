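"""Exception hierarchy for ssmholo."""


class SSMHoloError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(SSMHoloError, ValueError):
    """An argument violates a documented precondition."""


class DimensionMismatchError(InvalidArgumentError):
    """Array dimensions are inconsistent between operands."""


class InvalidDataError(SSMHoloError, ValueError):
    """Input data is malformed (non-finite, wrong pixel count, ...)."""


class DegenerateReferenceError(SSMHoloError):
    """Reference intensity vanishes on some pixels; calibration cannot divide by |R|."""


class DegenerateSpectrumError(SSMHoloError):
    """Leading eigenvalues are (numerically) tied; retrieval is ill-posed."""


class FormatError(SSMHoloError):
    """A file container is missing required datasets or attributes."""


class ResourceError(SSMHoloError):
    """Requested problem size exceeds the configured memory budget."""
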