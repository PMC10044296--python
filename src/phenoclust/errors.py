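"""Shared exception types."""


class PhenoclustError(Exception):
    """Base class for package errors."""


class ConfigError(PhenoclustError):
    """Invalid configuration (instrument spec, generator config, pipeline config)."""


class RegistryError(ConfigError):
    """Malformed item registry (duplicate ids, unknown instrument)."""


class SchemaError(PhenoclustError):
    """Input table does not match the registered item layout."""


class ImputationError(PhenoclustError):
    """Imputation cannot proceed (e.g. a fully-missing item column)."""
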