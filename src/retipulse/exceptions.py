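"""Exception hierarchy shared across the package."""


class RetipulseError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(RetipulseError, ValueError):
    """A configuration field is missing, out of range, or inconsistent."""


class DomainError(RetipulseError, ValueError):
    """An input value lies outside the mathematical domain of an operation."""


class FormatError(RetipulseError, ValueError):
    """Input files or arrays violate a structural contract (shape, dtype)."""


class DegenerateDataError(RetipulseError, ValueError):
    """The data admit no meaningful estimate (empty template, constant
    predictor, too few samples)."""


class SingularDesignError(RetipulseError, ValueError):
    """The regression design matrix is rank-deficient."""


class ConvergenceError(RetipulseError, RuntimeError):
    """An iterative estimation procedure failed to converge."""

    def __init__(self, message, bracket=None):
        super().__init__(message)
        self.bracket = bracket


class ProjectionError(RetipulseError, ValueError):
    """A point could not be projected onto a vessel centerline."""
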