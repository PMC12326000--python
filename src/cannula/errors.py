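"""Exception hierarchy shared by all analysis stages."""


class CannulaError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CannulaError):
    """A file could not be parsed in the declared format."""


class ValidationError(CannulaError):
    """Parsed data violate a domain invariant (duplicates, bad values...)."""


class InsufficientDataError(CannulaError):
    """Too few observations for the requested computation."""


class NoBindingError(InsufficientDataError):
    """A titration shows no shift response at all; a K_D fit is meaningless."""


class ConfigurationError(CannulaError):
    """A required user-supplied setting is missing or inconsistent."""
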