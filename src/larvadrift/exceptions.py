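"""Exception types shared across the package."""


class LarvadriftError(Exception):
    """Base class for package errors."""


class ParameterError(LarvadriftError, ValueError):
    """A function argument is outside its valid range."""


class ConfigurationError(LarvadriftError, ValueError):
    """Inconsistent or invalid configuration (grids, boxes, policies...)."""


class FormatError(LarvadriftError, ValueError):
    """A file does not conform to the expected schema."""
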