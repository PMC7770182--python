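"""Exception types used across the package."""


class GrnForestError(Exception):
    """Base class for all package errors."""


class ParseError(GrnForestError, ValueError):
    """A file could not be parsed (malformed row, non-numeric cell, ...)."""


class ValidationError(GrnForestError, ValueError):
    """An input violated a documented precondition or invariant."""
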