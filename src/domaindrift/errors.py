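"""Exception hierarchy shared across the package."""


class DomainDriftError(Exception):
    """Base class for all package-specific errors."""


class ParseError(DomainDriftError):
    """Malformed input text. ``position`` is a 0-based character or record offset."""

    def __init__(self, message: str, position: int | None = None):
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)
        self.position = position


class DuplicateIdError(ParseError):
    pass


class AlphabetError(ParseError):
    pass


class AlignmentError(DomainDriftError):
    """Records that do not form a valid alignment."""


class UndefinedIdentityError(DomainDriftError):
    """Percent identity has a zero denominator (no mutually ungapped columns)."""


class SaturationError(DomainDriftError):
    """A distance correction left its log domain (p too large)."""
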