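"""Exception hierarchy shared across the package."""


class TractlinkError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(TractlinkError):
    """A required column is absent or a column mapping is inconsistent."""


class CohortValidationError(TractlinkError):
    """A cohort table violates one of its invariants (bounds, uniqueness, NA)."""


class ParseError(TractlinkError):
    """A cell could not be parsed as the declared type."""


class ConfigError(TractlinkError):
    """A configuration object is internally inconsistent or infeasible."""


class ConvergenceError(TractlinkError):
    """An iterative fit did not converge within its iteration budget."""

    def __init__(self, message: str, last_delta: float | None = None):
        super().__init__(message)
        self.last_delta = last_delta


class SingularMatrixError(TractlinkError):
    """A linear system is singular / rank deficient."""
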