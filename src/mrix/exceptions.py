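"""Package-level exception hierarchy."""


class MRIxError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(MRIxError):
    """Invalid simulation or scoring configuration."""


class SchemaError(MRIxError):
    """Cohort table does not conform to the cohort schema."""


class FitError(MRIxError):
    """A model fit could not be performed on the given data."""
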