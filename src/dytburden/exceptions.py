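"""Exception types shared across the package."""


class DytBurdenError(Exception):
    """Base class for all package errors."""


class ValidationError(DytBurdenError):
    """Raised when an input file or in-memory object violates its contract."""


class SchemaError(ValidationError):
    """Raised when a table is missing required columns or has malformed values."""


class NoTestError(DytBurdenError):
    """Raised when an association test is degenerate (no variants / zero variance).

    Callers that scan many gene cells catch this and record the cell as
    *untested*, which is deliberately distinct from a p-value of 1.
    """


class ConvergenceError(DytBurdenError):
    """Raised when the logistic null model fails to converge or separates."""
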