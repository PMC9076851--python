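"""Exception hierarchy shared by all netpharm modules."""


class NetpharmError(Exception):
    """Base class for all netpharm-specific errors."""


class ValidationError(NetpharmError, ValueError):
    """An argument or object violates a documented precondition or invariant."""


class SchemaError(NetpharmError, ValueError):
    """A table or file is structurally valid but lacks required columns/fields."""


class ParseError(NetpharmError, ValueError):
    """A file could not be parsed; carries the offending location when known."""

    def __init__(self, message: str, *, line: int | None = None,
                 column: str | None = None):
        loc = []
        if line is not None:
            loc.append(f"line {line}")
        if column is not None:
            loc.append(f"column {column!r}")
        if loc:
            message = f"{message} ({', '.join(loc)})"
        super().__init__(message)
        self.line = line
        self.column = column
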