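"""Typed exceptions shared across the package."""


class EchoAugError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(EchoAugError, ValueError):
    """An argument violates a documented precondition."""


class TimestepRangeError(EchoAugError, IndexError):
    """A diffusion timestep lies outside the valid range."""


class ContractError(EchoAugError):
    """A callable violated its declared input/output contract."""


class DetectionError(EchoAugError):
    """Sector geometry could not be estimated from the image."""


class GenerationError(EchoAugError):
    """Synthetic sample generation failed after the allowed redraws."""


class UndefinedMetricError(EchoAugError):
    """The metric is undefined for the given inputs (e.g. empty label set)."""


class UndefinedTestError(EchoAugError):
    """The statistical test is undefined for the given inputs."""


class PipelineFailureError(EchoAugError):
    """All candidate computations in a pipeline stage failed."""


class LoadError(EchoAugError):
    """A file could not be read as a supported sample format."""


class ConfigError(EchoAugError):
    """A configuration file violates the schema."""
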