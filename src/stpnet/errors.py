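"""Exception hierarchy.

Validation problems (bad identifiers, malformed files, inconsistent
configurations) raise :class:`ValidationError` subclasses so callers can
distinguish user-input errors from genuine runtime failures.
"""


class StpnetError(Exception):
    """Base class for all package errors."""


class ValidationError(StpnetError):
    """Input violates a documented contract."""


class InvalidIdentifierError(ValidationError):
    """Empty or otherwise unusable protein identifier."""


class ParseError(ValidationError):
    """Malformed record in a network or score file."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class LookupNodeError(StpnetError):
    """A referenced node is not present in the network/matrix."""


class ConfigError(ValidationError):
    """Inconsistent synthetic-network or search configuration."""


class DegenerateBackgroundError(StpnetError):
    """Background standard deviation is zero; corrected score undefined."""


class GenerationError(StpnetError):
    """A synthetic-data generator could not satisfy its contract."""
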