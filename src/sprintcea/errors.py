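"""Exception hierarchy shared across the package."""


class SprintCeaError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(SprintCeaError):
    """Invalid model or population configuration (non-PSD matrix, bad range, ...)."""


class FormatError(SprintCeaError):
    """Malformed input file (missing column, unreadable table)."""


class RowError(FormatError):
    """A single row of an input table could not be parsed.

    Attributes
    ----------
    row_index : int
        Zero-based data-row index of the offending row.
    """

    def __init__(self, row_index: int, message: str):
        self.row_index = row_index
        super().__init__(f"row {row_index}: {message}")


class EstimateError(SprintCeaError):
    """An estimate is undefined (e.g. empty population)."""


class MissingFieldError(SprintCeaError):
    """A covariate required by a screening step is absent."""

    def __init__(self, field: str, step: str):
        self.field = field
        self.step = step
        super().__init__(f"field {field!r} required by step {step!r} is missing")


class DomainError(SprintCeaError):
    """An argument lies outside the mathematical domain of an operation."""


class InternalConsistencyError(SprintCeaError):
    """Bug trap: the simulation requested an impossible state transition."""
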