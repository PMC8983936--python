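"""Exception types shared across the package."""


class QWAError(Exception):
    """Base class for package errors."""


class ParameterError(QWAError, ValueError):
    """A configuration or function parameter is invalid."""


class ValidationError(QWAError, ValueError):
    """Input table failed validation.

    Carries the offending row number (1-based, counting data rows after the
    header) where one can be attributed.
    """

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"{message} (row {row})"
        super().__init__(message)


class SeriesTooShortError(QWAError, ValueError):
    """A time series is too short for the requested operation."""
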