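"""Exception hierarchy."""


class PhageCodonError(Exception):
    """Base class for all package errors."""


class ParseError(PhageCodonError):
    """A file could not be parsed in the expected dialect."""


class ValidationError(PhageCodonError):
    """Parsed content violates a domain invariant."""


class FrameError(PhageCodonError):
    """A CDS length is not a multiple of three."""


class UndefinedMetricError(PhageCodonError):
    """A metric has no defined value for the given input."""
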