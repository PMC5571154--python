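"""Exception hierarchy for immigratio.

All errors raised by the package derive from :class:`ImmigratioError` so that
callers (and the CLI) can catch package failures without masking bugs.
"""


class ImmigratioError(Exception):
    """Base class for all immigratio errors."""


class SchemaError(ImmigratioError):
    """A table does not have the required columns / layout."""


class ParseError(ImmigratioError):
    """A cell or string could not be parsed (coordinates included where known)."""


class InvariantError(ImmigratioError):
    """Data violates a documented invariant (e.g. enum rules, duplicates)."""


class ArgumentError(ImmigratioError):
    """An argument is outside its documented range."""


class EmptyResultError(ImmigratioError):
    """An operation produced an empty result where that is not allowed."""
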