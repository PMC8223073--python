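"""Exception hierarchy shared across the package."""


class WeightGradeError(Exception):
    """Base class for all package errors."""


class SchemaError(WeightGradeError):
    """A delimited file does not match the documented column schema."""


class ParseError(WeightGradeError):
    """A cell could not be parsed; message names row and column."""


class ValidationError(WeightGradeError):
    """One or more records violate their invariants.

    ``diagnostics`` is a list of (row_index, field, message) tuples; row
    indices are zero-based positions in the input table.
    """

    def __init__(self, message: str, diagnostics: list | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


class DomainError(WeightGradeError):
    """An argument lies outside the mathematical domain of an operation."""


class ProtocolError(WeightGradeError):
    """Raw measurements violate the measurement protocol (e.g. <3 replicates)."""


class AssignmentError(WeightGradeError):
    """A player cannot be assigned to any category band."""


class HarmonizationError(WeightGradeError):
    """Percentile cut-points cannot be harmonized into contiguous bands."""
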