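"""Exception hierarchy.

All user-facing failures derive from :class:`PoaSankeyError` so the CLI can
map them to exit code 2; anything else is an internal error (exit 1).
"""


class PoaSankeyError(Exception):
    """Base class for input/validation errors."""


class FormatDetectionError(PoaSankeyError):
    """Raised when an alignment file matches none of the known formats."""


class AlignmentValidationError(PoaSankeyError):
    """Raised when parsed alignment content violates the alignment invariants."""


class TreeParseError(PoaSankeyError):
    """Raised on malformed Newick input."""


class TreeAlignmentMismatchError(PoaSankeyError):
    """Raised when tree leaf labels and alignment ids differ."""


class GraphIntegrityError(PoaSankeyError):
    """Raised when a POA graph violates its structural invariants."""


class LookupErrorPoa(PoaSankeyError):
    """Raised on unknown node / sequence / tree-node references."""


class LayoutRangeError(PoaSankeyError):
    """Raised when a requested column range falls outside the graph."""
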