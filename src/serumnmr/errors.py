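"""Exception hierarchy shared across the pipeline.

The CLI maps these onto exit codes: ConfigError -> 2, DataError -> 3,
FitError -> 4.
"""


class PipelineError(Exception):
    """Base class for all serumnmr errors."""


class ConfigError(PipelineError):
    """Invalid configuration value (counts, widths, split numbers...)."""


class DataError(PipelineError):
    """Malformed or degenerate input data."""


class ParseError(DataError):
    """A reference table or spectrum file could not be parsed."""


class ReferencingError(DataError):
    """No qualifying lactate doublet found in the calibration window."""


class CoverageError(DataError):
    """A spectrum does not cover the requested binning range."""


class NormalizationError(DataError):
    """A sample has no positive signal to normalize against."""


class QuantificationError(DataError):
    """A metabolite's signature windows are unusable (e.g. fully masked)."""


class LeakageError(DataError):
    """Train and validation sets share sample ids."""


class DependencyError(DataError):
    """A required upstream artifact (e.g. a fitted model) is missing."""


class FitError(PipelineError):
    """A latent-variable model could not be fitted."""


class FoldError(FitError):
    """Cross-validation folds cannot be formed (k too large, etc.)."""
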