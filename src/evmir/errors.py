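"""Exception hierarchy for the pipeline.

Errors are split by stage so callers (and the CLI) can name the failing
stage without string-matching messages.
"""


class EvmirError(Exception):
    """Base class for all package errors."""


class PlateFormatError(EvmirError):
    """A plate or metadata file does not follow the documented CSV dialect."""


class ValidationError(EvmirError):
    """Input data violate a structural invariant (roles, cohorts, duplicates)."""


class SizingError(EvmirError):
    """A synthetic design asks for more samples than the plates can hold."""


class ConfigurationError(EvmirError):
    """A required target or setting is missing from the run configuration."""


class CalibrationError(EvmirError):
    """Inter-plate calibration cannot be computed or applied."""


class InsufficientDataError(EvmirError):
    """Too few observations for the requested statistic."""


class AlignmentError(EvmirError):
    """Feature sets of two cohorts cannot be aligned by name."""


class StratificationError(EvmirError):
    """A class is too small to stratify the requested split."""
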