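"""Exception hierarchy shared across the pipeline stages."""


class CorelncError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(CorelncError):
    """A configuration value violates its documented constraints."""


class DataError(CorelncError):
    """An input carries values its contract forbids (negative counts,
    out-of-range probabilities, degenerate groups, ...)."""


class ParseError(CorelncError):
    """A text input file could not be parsed; carries the line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class FitError(CorelncError):
    """A model fit is impossible (rank-deficient design, ...)."""
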