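"""Exception hierarchy shared across the package."""


class NircalibError(Exception):
    """Base class for all package errors."""


class ConfigurationError(NircalibError, ValueError):
    """An invalid configuration value (bad truncation bounds, bad code, ...)."""


class DataError(NircalibError, ValueError):
    """Input data violates a contract (shape, range, missing samples, ...)."""


class ParseError(NircalibError, ValueError):
    """A file could not be parsed; the message names the offending line."""
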