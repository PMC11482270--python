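"""Exception hierarchy shared across the pipeline modules."""


class LiverscopeError(Exception):
    """Base class for all pipeline errors."""


class FormatError(LiverscopeError):
    """Input file or array does not have the expected structure."""


class SchemaError(LiverscopeError):
    """A required column or label is missing, or labels do not align."""


class EmptyAtlasError(LiverscopeError):
    """A filtering step removed every cell or every gene."""


class ConfigurationError(LiverscopeError):
    """A parameter or auxiliary table is invalid or empty."""


class NormalizationError(LiverscopeError):
    """A sample or cell has zero library size and cannot be scaled."""


class DegenerateSignatureError(LiverscopeError):
    """Fewer than two cell types: a centered signature is undefined."""


class IncompatibilityError(LiverscopeError):
    """Two inputs share no genes and cannot be combined."""


class InsufficientReplicationError(LiverscopeError):
    """A group has fewer than two observations; no t test possible."""


class ThresholdingError(LiverscopeError):
    """The intensity histogram never became bimodal; no threshold exists."""


class PlacementError(LiverscopeError):
    """Synthetic droplets could not be placed without touching."""


class UndefinedRatioError(LiverscopeError):
    """Denominator stain covers zero area; the area ratio is undefined."""
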