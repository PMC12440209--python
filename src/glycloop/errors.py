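"""Exception hierarchy for glycloop."""


class GlycloopError(Exception):
    """Base class for all package errors."""


class LoadError(GlycloopError):
    """A patient log could not be parsed or validated."""


class FeatureError(GlycloopError):
    """A feature could not be computed from the given window."""


class SimulationError(GlycloopError):
    """The virtual-patient simulation produced a non-finite state."""


class ProfilingError(GlycloopError):
    """Clustering/profiling failed (empty subset, dimension mismatch...)."""


class TrainingError(GlycloopError):
    """A subgroup classifier could not be trained."""


class MetricError(GlycloopError):
    """An evaluation metric is undefined for the given inputs."""


class TrendError(GlycloopError):
    """The pre-meal CGM slope could not be estimated."""


class ConfigError(GlycloopError):
    """Run configuration failed validation."""
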