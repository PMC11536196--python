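"""Exception hierarchy for symptomnet.

Every failure mode raised by the library derives from :class:`SymptomNetError`
so callers (and the CLI) can distinguish usage errors from data problems.
"""


class SymptomNetError(Exception):
    """Base class for all symptomnet errors."""


class SchemaError(SymptomNetError):
    """The input file or column-mapping schema is malformed (missing column, etc.)."""


class DataValidationError(SymptomNetError):
    """A data cell or structure violates the binary-criteria contract."""


class ParameterError(SymptomNetError):
    """A parameter is outside its admissible range."""


class EmptyInputError(SymptomNetError):
    """An input file or dataset contains no rows."""


class UndefinedReliabilityError(SymptomNetError):
    """Reliability coefficient undefined (zero total-score variance)."""


class InfeasibleStructureError(SymptomNetError):
    """A requested latent structure does not define a valid (positive-definite)
    correlation matrix, or truncation makes sampling practically impossible."""


class DegenerateColumnError(SymptomNetError):
    """A criterion column is constant, so its correlations are undefined."""


class SingularMatrixError(SymptomNetError):
    """Correlation matrix is not positive-definite beyond the ridge tolerance."""


class InsufficientSampleError(SymptomNetError):
    """Sample size too small for the requested partial-correlation test."""


class DisconnectedGraphError(SymptomNetError):
    """A path-based metric was requested on a disconnected graph."""
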