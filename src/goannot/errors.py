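"""Exception hierarchy shared by all goannot modules."""


class GoannotError(Exception):
    """Base class for all goannot errors."""


class ParseError(GoannotError):
    """A file did not conform to its declared format.

    Carries enough context (line number or stanza id) to locate the
    offending record.
    """

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class ValidationError(GoannotError):
    """Input parsed but violates a semantic invariant (cycle, bad reference)."""


class LookupFailure(GoannotError, KeyError):
    """An identifier did not resolve (unknown GO term, node label, ...)."""

    def __str__(self) -> str:  # KeyError quotes its message; keep it readable
        return Exception.__str__(self)


class UsageError(GoannotError):
    """The caller combined arguments inconsistently."""
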