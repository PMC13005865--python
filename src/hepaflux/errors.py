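"""Exception hierarchy shared by all pipeline stages."""


class HepafluxError(Exception):
    """Base class for all package errors."""


class SchemaError(HepafluxError):
    """A required field or column is missing from an on-disk dataset."""


class DataValidationError(HepafluxError):
    """An in-memory object violates a structural invariant."""


class UnitError(HepafluxError):
    """A measurement carries an unknown or disallowed unit."""


class AlignmentError(HepafluxError):
    """Two series that must share a time grid do not."""


class ConfigError(HepafluxError):
    """A configuration value is out of its admissible range."""


class IdentifiabilityError(HepafluxError):
    """A fit was requested with more freedom than the data can support."""


class FitError(HepafluxError):
    """Numerical failure during model fitting or simulation."""
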