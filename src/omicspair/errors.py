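"""Exception hierarchy shared across the pipeline."""


class OmicspairError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(OmicspairError):
    """A file or table violates the expected on-disk format."""


class UsageError(OmicspairError):
    """An operation was called on inputs that violate its contract."""


class ConfigError(OmicspairError):
    """A configuration value is missing, malformed, or infeasible."""
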