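"""Exception types shared across the pipeline."""


class CufflessBPError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CufflessBPError):
    """Invalid or inconsistent configuration (bad key, infeasible quota, ...)."""


class QuotaError(ConfigurationError):
    """A generated cohort could not satisfy the configured BP-distribution quotas."""


class InsufficientBeatsError(CufflessBPError):
    """Fewer matched beats than the operation requires."""


class FlatSignalError(CufflessBPError):
    """Zero amplitude range where a normalizable waveform was expected."""


class WaveletError(CufflessBPError):
    """Non-finite output from the continuous wavelet transform."""


class ExtremaError(CufflessBPError):
    """Too few extrema in the second-derivative pulse waveform."""


class MissingFeatureError(CufflessBPError):
    """A required feature or demographic field is absent; the message names it."""


class IntegrityError(CufflessBPError):
    """A persisted model archive violates its schema (e.g. wrong member count)."""


class MissingChannelError(CufflessBPError):
    """A signal file lacks a required channel/column."""


class RateMismatchError(CufflessBPError):
    """Sampling rate of an input file disagrees with the run configuration."""
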