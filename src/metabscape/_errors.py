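"""Exception hierarchy shared across the package."""


class MetabscapeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MetabscapeError):
    """A configuration value is missing, malformed or unresolvable."""


class ValidationError(MetabscapeError):
    """Input data violates a contract (negative values, bad labels, ...)."""
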