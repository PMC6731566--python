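"""Exception hierarchy for trigrec."""


class TrigrecError(Exception):
    """Base class for all trigrec errors."""


class ParseError(TrigrecError):
    """A corpus file line/row could not be parsed; carries the offending location."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class IntegrityError(TrigrecError):
    """An annotation violates its offset/surface invariants."""


class AmbiguityError(TrigrecError):
    """A token overlaps two trigger annotations of different types."""


class PlanError(TrigrecError):
    """A transfer plan references a block whose shapes conflict or is missing."""


class ConfigError(TrigrecError):
    """An invalid configuration value."""
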