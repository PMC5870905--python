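"""Exception types shared across the package."""


class RfsolveError(Exception):
    """Base class for all package-specific errors."""


class NewickParseError(RfsolveError):
    """Malformed newick input.

    Carries the 1-based line and column of the offending character when the
    underlying reader reports them.
    """

    def __init__(self, message: str, line: int | None = None, column: int | None = None):
        self.line = line
        self.column = column
        if line is not None:
            message = f"{message} (line {line}, column {column})"
        super().__init__(message)


class DuplicateLabelError(RfsolveError):
    """A tree carries the same leaf label more than once (multi-copy inputs
    are rejected; every source tree must have at most one copy of each leaf)."""


class LeafsetError(RfsolveError):
    """Leafset precondition violated (mismatch, unknown label, bad subset)."""


class InfeasibleConstraintsError(RfsolveError):
    """The allowed-bipartition set admits no binary tree on the full taxon set."""
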