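"""Exception hierarchy shared across the pipeline."""


class IdccError(Exception):
    """Base class for all package-specific errors."""


class FormatError(IdccError):
    """A file exists but cannot be decoded in a supported format."""


class ParseError(IdccError):
    """A text file (annotations, counts) violates its dialect."""


class ValidationError(IdccError):
    """Input data violates a documented precondition or invariant."""


class CapabilityError(IdccError):
    """A requested backend or optional dependency is unavailable."""
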