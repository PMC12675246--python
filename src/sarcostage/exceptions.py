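"""Exception hierarchy shared across the package."""


class SarcostageError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SarcostageError):
    """A configuration object is invalid; the message names the field."""


class InputValidationError(SarcostageError, ValueError):
    """An input value is outside its documented domain."""


class IncompleteResponsesError(InputValidationError):
    """Questionnaire responses contain missing items where none are allowed."""


class DegenerateInputError(SarcostageError):
    """The statistic is undefined for this input (e.g. zero variance)."""


class NotStageableError(InputValidationError):
    """Participant cannot be assigned a progression stage (Healthy band)."""


class ConvergenceError(SarcostageError):
    """Iterative solver failed to converge within its iteration budget."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class RatingError(InputValidationError):
    """An indicator could not be rated; the message names the leaf."""
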