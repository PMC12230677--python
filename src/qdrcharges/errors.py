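"""Exception hierarchy for the qdrcharges package."""


class QdrError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(QdrError):
    """A file does not conform to the documented exchange schema."""


class ConsistencyError(QdrError):
    """Input data violates a partition invariant (e.g. charge sum, mirrored
    pairs with conflicting overlap populations)."""


class ValidationError(QdrError):
    """An argument violates a documented precondition."""


class ContractError(QdrError):
    """An internal call violated a dimension/kind contract."""


class SolverError(QdrError):
    """A block linear solve failed to converge; carries the solve report."""

    def __init__(self, message, report=None):
        super().__init__(message)
        self.report = report


class UnsupportedOperationError(QdrError):
    """Operation undefined for this input (e.g. molecular multipoles of a
    periodic cell)."""
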