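"""Exception types shared across the package."""


class CnascapeError(Exception):
    """Base class for all package-specific errors."""


class ParseError(CnascapeError, ValueError):
    """A file could not be parsed; message carries file/line/column context."""


class ValidationError(CnascapeError, ValueError):
    """Parsed content violates a domain invariant."""
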