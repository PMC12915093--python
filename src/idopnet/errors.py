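"""Diagnostic exception types raised across the pipeline."""


class IdopnetError(Exception):
    """Base class for all package-specific errors."""


class DataValidationError(IdopnetError):
    """Input data violates a dataset invariant (negative value, bad shape...)."""


class DuplicateGeneError(DataValidationError):
    """Gene identifiers are not unique."""


class NegativeValueError(DataValidationError):
    """Expression matrix contains a negative entry."""


class MetadataMismatchError(DataValidationError):
    """Sample metadata does not match the matrix columns."""


class FitError(IdopnetError):
    """A model fit could not be carried out on the given data."""


class NotPositiveDefiniteError(IdopnetError):
    """An assembled covariance matrix is not positive definite."""
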