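"""Exception hierarchy shared by all pipeline stages."""


class TbarsError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(TbarsError):
    """Input table is missing a required column."""


class TableParseError(TbarsError):
    """A row could not be parsed; carries 1-based line numbers."""

    def __init__(self, message: str, lines: list[int] | None = None):
        super().__init__(message)
        self.lines = lines or []


class EmptyDatasetError(TbarsError):
    """Input contained no records."""


class NormalizationError(TbarsError):
    """A measurement group cannot be converted to percent-of-initial scale."""


class DomainError(TbarsError, ValueError):
    """A value is outside the mathematical domain of an operation."""


class InsufficientDataError(TbarsError):
    """Fewer observations than the estimator requires."""


class DegenerateDesignError(TbarsError):
    """Design matrix carries no information (e.g. a single distinct x)."""


class FitFailureError(TbarsError):
    """Nonlinear fit failed to converge; carries the best grid point found."""

    def __init__(self, message: str, best_params: tuple | None = None):
        super().__init__(message)
        self.best_params = best_params


class CollinearityError(TbarsError):
    """Regression design is rank deficient; names the offending columns."""

    def __init__(self, message: str, columns: list[str] | None = None):
        super().__init__(message)
        self.columns = columns or []


class ConfigurationError(TbarsError):
    """Pipeline configuration is inconsistent with the supplied data."""


class EncodingError(TbarsError):
    """A record cannot be encoded into the model's feature space."""


class SplitError(TbarsError):
    """Train/validation/test partition is degenerate."""


class TrainingFailureError(TbarsError):
    """Network training produced a non-finite loss."""
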