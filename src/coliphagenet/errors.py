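"""Exception hierarchy shared by all pipeline stages."""


class ColiphageNetError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(ColiphageNetError):
    """Invalid configuration value or unknown configuration key."""


class ValidationError(ColiphageNetError):
    """Invalid input value (out of range, empty sequence, ...)."""


class DataError(ColiphageNetError):
    """Inconsistent or malformed input data (unknown ids, duplicates, ...)."""


class IntegrityError(ColiphageNetError):
    """Cross-stage consistency violation detected while summarising."""


class ParseError(DataError):
    """Malformed row in a tabular input; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
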