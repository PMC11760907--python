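"""Exception types shared across the package."""


class DimensionMismatchError(ValueError):
    """Two arrays that must agree spatially do not."""


class ConfigurationError(ValueError):
    """A model/experiment configuration is inconsistent."""


class UndefinedMetricError(ValueError):
    """A metric is mathematically undefined for the given inputs."""


class TrainingDivergedError(RuntimeError):
    """Training produced a non-finite loss."""
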