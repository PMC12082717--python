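"""Exception hierarchy for the preictal profiling pipeline.

Every pipeline stage raises a subclass of :class:`PipelineError`, so batch
runs can isolate per-record failures and record the failing stage.
"""


class PipelineError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(PipelineError):
    """A file could not be parsed (truncated/corrupt EDF, bad JSON/YAML)."""


class ContentError(PipelineError):
    """A file parsed but its content is unusable (e.g. no EEG channels)."""


class ParameterError(PipelineError):
    """An argument is outside its valid domain."""


class DegenerateWindowError(PipelineError):
    """A feature was requested on a constant / zero-variance window."""


class CoverageError(PipelineError):
    """The recording does not cover a required time span."""


class DataError(PipelineError):
    """Not enough usable data (e.g. too few training windows)."""


class LabelingError(PipelineError):
    """A classification dataset ended up with a single class."""


class FitError(PipelineError):
    """A model fit failed to converge or produced non-finite coefficients."""


class ConfigError(PipelineError):
    """Missing or inconsistent run configuration."""
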