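"""Exception types shared across the package."""


class TamspatialError(Exception):
    """Base class for package errors."""


class ConfigError(TamspatialError, ValueError):
    """Invalid simulation or pipeline configuration."""


class SchemaError(TamspatialError, ValueError):
    """Cell-table / matrix file does not match the expected dialect."""


class DataError(TamspatialError, ValueError):
    """Input data violate an operation's precondition."""


class DependencyError(TamspatialError, RuntimeError):
    """A pipeline stage was requested before its upstream artifact exists."""
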