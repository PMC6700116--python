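"""Exception hierarchy shared across the package."""


class PastroError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PastroError, ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(PastroError, ValueError):
    """Parsed data violates a container invariant (duplicates, negatives, ...)."""
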