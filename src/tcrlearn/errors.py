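"""Exception hierarchy shared across the pipeline."""


class TcrlearnError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TcrlearnError):
    """A user-supplied option is invalid (unknown method, missing label column, ...)."""


class ValidationError(TcrlearnError):
    """Input data violates the repertoire-matrix contract (negative counts, ...)."""


class FormatError(TcrlearnError):
    """A file does not match the expected on-disk format."""


class DegenerateSampleError(TcrlearnError):
    """A sample carries no reads, or a class is too small for the requested design."""


class ContractError(TcrlearnError):
    """Two pipeline artifacts disagree (feature-name mismatch, sample mismatch, ...)."""


class ResourceError(TcrlearnError):
    """A computation would exceed an explicit resource cap (e.g. graph node cap)."""


class ModelFormatError(TcrlearnError):
    """A model container file is corrupted or was written by an incompatible version."""


class NonTransferableFeatureError(TcrlearnError):
    """The model depends on features (t-SNE axes) that cannot be mapped onto new samples."""


class EmptySelectionError(TcrlearnError):
    """Feature selection produced an empty feature set."""
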