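"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Input data violates a structural contract (shape, range, NaNs)."""


class ConfigError(ValueError):
    """A configuration object is internally inconsistent."""


class SynchronizationError(RuntimeError):
    """Event trains share no coincidences at any admissible lag."""


class TrainingDivergedError(RuntimeError):
    """Optimization produced a non-finite loss."""


class MetricUndefinedError(RuntimeError):
    """A metric has no value for the given inputs (e.g. no events)."""
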