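"""Exception hierarchy for spliceconv."""


class SpliceconvError(Exception):
    """Base class for all spliceconv errors."""


class EncodingError(SpliceconvError):
    """A sequence contains a character outside the normalized alphabet."""


class DecodingError(SpliceconvError):
    """A one-hot row is neither a basis vector nor the zero vector."""


class AnnotationError(SpliceconvError):
    """A site-annotation row is malformed or references an unknown contig."""


class DatasetError(SpliceconvError):
    """A dataset request cannot be satisfied (shortfall, bad ratio, parse failure)."""


class ConfigError(SpliceconvError):
    """An invalid configuration value (probability vectors, ratios, grids)."""


class CatalogError(SpliceconvError):
    """An unknown architecture name was requested."""


class ShapeError(SpliceconvError):
    """Tensor shapes do not match the owning architecture."""


class AveragingError(SpliceconvError):
    """Two weight sets share no structurally matching layers."""


class TrainingError(SpliceconvError):
    """Training cannot proceed (empty set, class too small for k folds)."""


class DivergenceError(TrainingError):
    """The loss became non-finite during training."""


class ModelFormatError(SpliceconvError):
    """A saved model bundle is corrupt or has an unsupported format version."""


class EvaluationError(SpliceconvError):
    """Inconsistent inputs to an evaluation routine."""
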