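"""Exception types raised by the pipeline."""


class GazecourseError(Exception):
    """Base class for all package errors."""


class ConfigError(GazecourseError, ValueError):
    """Invalid configuration value."""


class DataError(GazecourseError, ValueError):
    """Malformed or inconsistent input data."""


class SchemaError(DataError):
    """An input table is missing required columns or has bad values."""


class PipelineError(GazecourseError, RuntimeError):
    """An end-to-end run cannot proceed (e.g. no analyzable trials)."""
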