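"""Exception hierarchy shared across the toolkit."""


class OnkoError(Exception):
    """Base class for all toolkit errors."""


class VariantParseError(OnkoError, ValueError):
    """A variant query string could not be parsed.

    ``token`` names the first offending token so callers can point at it.
    """

    def __init__(self, message: str, token: str = ""):
        super().__init__(message)
        self.token = token


class ValidationError(OnkoError, ValueError):
    """A parsed object violates a structural invariant."""


class FormatError(OnkoError, ValueError):
    """A file does not conform to its declared format."""


class ConfigError(OnkoError, ValueError):
    """A configuration file or value is malformed."""
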