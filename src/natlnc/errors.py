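"""Exception hierarchy shared across the package."""


class NatlncError(Exception):
    """Base class for all package errors."""


class ValidationError(NatlncError, ValueError):
    """An input object violates a documented invariant."""


class ParseError(NatlncError, ValueError):
    """A file could not be parsed; the message names the offending line/row."""


class ConfigurationError(NatlncError, ValueError):
    """A configuration value is inconsistent or infeasible."""
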