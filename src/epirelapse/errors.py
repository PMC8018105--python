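"""Exception hierarchy shared across the package."""


class EpirelapseError(Exception):
    """Base class for all package errors."""


class FormatError(EpirelapseError, ValueError):
    """A file or table does not conform to the expected layout."""


class ValidationError(EpirelapseError, ValueError):
    """Inputs are well-formed but violate a domain invariant."""


class ConfigError(EpirelapseError, ValueError):
    """A configuration value is out of its allowed range."""
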