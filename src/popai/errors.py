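"""Exception hierarchy shared across the package."""


class PopaiError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PopaiError):
    """A sensor file does not match the declared dialect."""


class IntegrityError(PopaiError):
    """File parsed but its content violates an invariant (overlaps,
    decreasing cumulative steps, inconsistent metadata)."""


class UnsupportedEpochError(PopaiError):
    """Counts epoch length incompatible with the requested aggregation."""


class ConfigurationError(PopaiError):
    """Invalid configuration (bad transition matrix, missing model, ...)."""


class EstimationError(PopaiError):
    """An estimator could not run (e.g. insufficient signal overlap)."""


class UndefinedScoreError(PopaiError):
    """A classification score is undefined (a class absent from the labels)."""


class FeatureError(PopaiError):
    """Feature extraction failed (NaN in signal, registry size mismatch)."""


class RegistryMismatchError(PopaiError):
    """Model and feature registry versions are incompatible."""


class InsufficientSampleError(PopaiError):
    """Too few paired observations for an agreement statistic."""
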