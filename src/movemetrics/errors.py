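"""Exception types shared across the package."""


class MovemetricsError(Exception):
    """Base class for all package errors."""


class FormatError(MovemetricsError):
    """Malformed input file; carries the 1-based line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(MovemetricsError):
    """Structurally parseable input that violates a domain invariant."""


class CapacityError(MovemetricsError):
    """More concurrent bodies than the 6-body tracking capacity."""
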