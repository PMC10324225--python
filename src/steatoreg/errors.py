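"""Exception hierarchy shared across the package."""


class SteatoregError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(SteatoregError):
    """A record violates a structural invariant (e.g. start >= end)."""


class SchemaError(SteatoregError):
    """A table is missing required columns."""


class PFMParseError(SteatoregError):
    """A position frequency matrix file could not be parsed."""


class ConfigurationError(SteatoregError):
    """Invalid configuration values."""


class SizingError(ConfigurationError):
    """Requested synthetic layout does not fit the genome."""


class AlignmentError(SteatoregError):
    """Two matrices that must share an index set do not."""


class UndefinedCallError(SteatoregError):
    """A measurement is undefined for the given inputs (e.g. 0/0)."""
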