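"""Exception hierarchy.

``UsageError`` maps to CLI exit code 2, ``DataError`` (and subclasses) to
exit code 1.
"""


class EditscanError(Exception):
    """Base class for all package errors."""


class UsageError(EditscanError):
    """Invalid option combination or out-of-range parameter."""


class DataError(EditscanError):
    """Problem with user-supplied data."""


class FormatError(DataError):
    """Malformed input file or sequence string."""


class QueryError(DataError):
    """Query could not be resolved against the genome / gene table."""


class RangeError(DataError):
    """Coordinates or indices outside the valid range."""
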