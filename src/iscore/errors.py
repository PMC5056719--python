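"""Exception hierarchy shared by all iscore modules."""


class IscoreError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(IscoreError):
    """A malformed input file; carries the path and 1-based line number."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        self.path = path
        self.line = line
        loc = ""
        if path is not None:
            loc = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + loc)


class DataError(IscoreError):
    """Semantically invalid data (duplicates, unknown genes, empty inputs)."""


class InfeasibleError(IscoreError):
    """A requested operation has no valid outcome (e.g. too few node pairs)."""
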