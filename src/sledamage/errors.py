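"""Exception hierarchy shared across the package."""


class SleDamageError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SleDamageError):
    """An invalid parameter or option (bad prevalence, non-positive size...)."""


class DataError(SleDamageError):
    """Input data violate a contract (non-binary flag, missing feature...)."""


class SchemaError(DataError):
    """A file does not match the expected column schema."""
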