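"""Exception hierarchy for the iristex pipeline."""


class IristexError(Exception):
    """Base class for all pipeline-specific errors."""


class GeometryError(IristexError):
    """A synthetic eye specification describes impossible geometry."""


class OutOfBoundsError(IristexError):
    """A sampling circle (partially) leaves the image."""


class NoCircleFoundError(IristexError):
    """The integro-differential search found no edge above the response floor."""


class ConfigError(IristexError):
    """An invalid configuration value (e.g. unknown wavelet name)."""


class EmptyGLCMError(IristexError):
    """The image is too small to contain any pixel pair at the requested offset."""


class EmptyGLRLMError(IristexError):
    """A run-length matrix without a single run."""


class SingleClassError(IristexError):
    """Feature ranking/evaluation needs both class labels present."""


class StratificationError(IristexError):
    """A class has fewer samples than cross-validation folds."""


class UndefinedAUCError(IristexError):
    """ROC AUC is undefined when only one class is present."""


class PipelineError(IristexError):
    """Every input image failed a pipeline stage."""
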