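"""Exception types shared across the package."""


class OpenLookError(ValueError):
    """Base class for all package-specific errors."""


class SchemaError(OpenLookError):
    """A required column is missing or a table violates the frame schema."""


class ParseError(OpenLookError):
    """A cell could not be parsed; message carries column and row."""


class ConfigError(OpenLookError):
    """Invalid configuration value."""


class AlignmentError(OpenLookError):
    """Protocol and frame table do not cover compatible time spans."""
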