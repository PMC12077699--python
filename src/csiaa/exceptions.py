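"""Exception hierarchy shared by all csiaa modules.

Loading problems are split into format vs. duplication errors so callers can
distinguish "the file is malformed" from "the file contradicts itself".
``UndefinedResultError`` signals a metric that cannot be computed from the
inputs at hand (e.g. too few amino acids for ΣV); it is never silently
converted to zero.
"""


class CsiaaError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(CsiaaError):
    """Input file or record does not match the expected layout."""


class DuplicationError(CsiaaError):
    """The same key (sample/amino acid/isotope, or depth) appears twice."""


class DomainError(CsiaaError):
    """An argument is outside the mathematical or physical domain."""


class UndefinedResultError(CsiaaError):
    """The requested quantity is undefined for these inputs."""
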