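"""Exception hierarchy.

Three error families map onto distinct CLI exit codes: configuration
problems (bad config files, invalid priors), data problems (malformed
tables, deficient designs, empty inputs), and numerical problems
(non-finite intermediate values).
"""


class AdhdDynamicsError(Exception):
    """Base class for all package errors."""


class ConfigError(AdhdDynamicsError):
    """Invalid configuration document or prior specification."""


class DataError(AdhdDynamicsError):
    """Invalid or unusable input data."""


class ParseError(DataError):
    """Malformed tabular or structured-text input; carries offending lines."""

    def __init__(self, message: str, lines: list[int] | None = None):
        self.lines = lines or []
        if self.lines:
            message = f"{message} (lines: {', '.join(map(str, self.lines))})"
        super().__init__(message)


class EmptyInputError(DataError):
    """An operation received an empty table or trial list."""


class ScheduleCoverageError(DataError):
    """A sampling time falls outside the context schedule."""


class IdentifiabilityError(DataError):
    """The observation design cannot identify the requested free parameters."""


class NumericalError(AdhdDynamicsError):
    """Non-finite values encountered during computation."""
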