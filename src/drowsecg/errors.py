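"""Exception hierarchy shared across the pipeline."""


class DrowsecgError(Exception):
    """Base class for all package errors."""


class ConfigurationError(DrowsecgError):
    """A configuration value violates its documented invariant."""


class SamplingRateError(ConfigurationError):
    """Sampling rate too low for the requested operation."""


class InsufficientDataError(DrowsecgError):
    """Not enough samples/beats/records for a well-defined result."""


class DataQualityError(DrowsecgError):
    """Data fails a quality contract (e.g. too many missing values)."""


class TrainingError(DrowsecgError):
    """Model training cannot proceed (e.g. single-class training set)."""
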