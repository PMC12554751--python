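"""Exception hierarchy: data errors (bad inputs) vs configuration errors."""


class PsermkitError(Exception):
    """Base class for all package errors."""


class DataError(PsermkitError):
    """Malformed input data (bad nucleotide symbols, mixed lengths, ...)."""


class ConfigError(PsermkitError):
    """Inconsistent or invalid configuration (unknown rounds, bad manifest, ...)."""
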