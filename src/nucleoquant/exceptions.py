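"""Exception hierarchy for the pipeline."""


class NucleoquantError(Exception):
    """Base class for all package errors."""


class SchemaError(NucleoquantError):
    """A table is missing a required column or has the wrong layout."""


class TableParseError(NucleoquantError):
    """A cell could not be parsed; carries the offending row number."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class InsufficientDataError(NucleoquantError):
    """Fewer observations than the operation requires."""


class WeightingError(NucleoquantError):
    """A weighting scheme cannot be applied to the given responses."""


class SingularDesignError(NucleoquantError):
    """The regression design has no unique solution."""


class DomainError(NucleoquantError):
    """An argument lies outside the mathematical domain of the operation."""


class ConfigurationError(NucleoquantError):
    """A required configuration item (e.g. a fitted curve) is missing."""
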