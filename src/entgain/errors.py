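"""Exception hierarchy shared across the package."""


class EntgainError(Exception):
    """Base class for all package-specific errors."""


class FormatError(EntgainError):
    """Malformed input file (ragged rows, bad token counts)."""


class DuplicateGeneError(FormatError):
    """The same gene identifier appears twice in one matrix."""


class DegenerateSeriesError(EntgainError):
    """A time series has zero variance and cannot be standardized."""


class ThresholdError(EntgainError):
    """Quantization thresholds violate l <= h."""


class InsufficientDataError(EntgainError):
    """No fully-observed aligned time point is available for a score."""


class LookupError_(EntgainError):
    """A requested gene is absent from the expression matrix."""
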