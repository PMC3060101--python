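"""Exception hierarchy."""


class DyndiffError(Exception):
    """Base class for all package errors."""


class ParseError(DyndiffError):
    """Malformed input file (ragged rows, duplicate ids, non-numeric cells)."""


class ValidationError(DyndiffError):
    """Inputs violate a structural contract (grid mismatch, missing t=0, ...)."""


class ConfigurationError(DyndiffError):
    """Invalid configuration values."""
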