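"""Exception hierarchy shared across the compression pipeline.

Every error raised on purpose by this package derives from
:class:`SRCompError`, so callers (notably the command-line layer) can map
failures to exit codes without matching on message strings.
"""


class SRCompError(Exception):
    """Base class for all errors raised by srcomp."""


class InvalidBaseError(SRCompError, ValueError):
    """A read contains a character outside the accepted alphabet."""


class UniformLengthError(SRCompError, ValueError):
    """A read's length differs from the fixed length of the collection."""


class SortednessError(SRCompError, ValueError):
    """A sequence required to be (strictly) non-decreasing is not."""


class TruncationError(SRCompError, ValueError):
    """A bit stream ended in the middle of a codeword."""


class ParseError(SRCompError, ValueError):
    """An input file is malformed for its declared format."""


class CorruptFileError(SRCompError, ValueError):
    """A compressed container fails structural or payload validation."""


class NotSRCompFileError(CorruptFileError):
    """The input does not start with the container magic tag."""


class VersionError(CorruptFileError):
    """The container declares an unsupported format version."""


class InfeasibleBudgetError(SRCompError, ValueError):
    """No partition depth can bring partitions under the memory budget."""
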