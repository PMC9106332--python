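"""Package-wide exception types."""


class ModinvarError(Exception):
    """Base class for package errors."""


class InvalidParameterError(ModinvarError, ValueError):
    """A parameter violates a documented precondition."""


class SamplingError(ModinvarError, RuntimeError):
    """Rejection sampling exceeded its attempt cap (infeasible threshold)."""


class TrainingError(ModinvarError, RuntimeError):
    """Training diverged; carries the history accumulated so far."""

    def __init__(self, message, history=None):
        super().__init__(message)
        self.history = history


class ConfigError(ModinvarError, ValueError):
    """A configuration file contains unknown keys or bad values."""


class UndefinedMetricError(ModinvarError, ValueError):
    """A metric is undefined for the given data (e.g. zero-variance trace)."""


class UnsupportedOperationError(ModinvarError, TypeError):
    """The operation does not apply to this model architecture."""
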