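"""Exception hierarchy shared across the package."""


class MultiROIError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MultiROIError):
    """A required column, option, or config key is missing or inconsistent."""


class CellTableParseError(MultiROIError):
    """A cell table row could not be parsed (carries the offending row index)."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class InsufficientDataError(MultiROIError):
    """Too few cells of the requested phenotype to compute a summary."""


class DegenerateWeightsError(MultiROIError):
    """All aggregation weights are zero (or sum to zero)."""


class DegeneratePredictorError(MultiROIError):
    """The aggregated summary is constant (or otherwise unusable) as a predictor."""


class ConvergenceError(MultiROIError):
    """An outcome-model fit failed to converge or was degenerate."""
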