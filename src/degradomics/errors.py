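"""Exception hierarchy shared across the package."""


class DegradomicsError(Exception):
    """Base class for all package errors."""


class FormatError(DegradomicsError, ValueError):
    """A file is structurally unreadable (empty FASTA, malformed table)."""


class ValidationError(DegradomicsError, ValueError):
    """A parsed value violates a domain invariant (alphabet, bounds)."""


class ConfigError(DegradomicsError, ValueError):
    """A parameter or configuration value is outside its documented domain."""


class StateError(DegradomicsError, RuntimeError):
    """An operation was invoked before a required preceding step."""
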