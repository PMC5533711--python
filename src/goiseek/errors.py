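"""Exception hierarchy.

All package-level failures derive from :class:`GoiseekError` so callers (and
the CLI) can distinguish domain errors from programming errors.
"""


class GoiseekError(Exception):
    """Base class for all errors raised by goiseek."""


class ParseError(GoiseekError):
    """A file could not be parsed (malformed cell, bad line, ...)."""


class ValidationError(GoiseekError):
    """An input violates a documented invariant or precondition."""


class AlignmentError(GoiseekError):
    """Two inputs that must share identifiers do not."""


class FormatError(GoiseekError):
    """A structured text file violates its format contract."""


class EmptyInputError(GoiseekError):
    """A file contained no parseable data."""
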