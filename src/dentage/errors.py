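"""Exception hierarchy shared across the package."""


class DentageError(Exception):
    """Base class for all package-specific errors."""


class InvalidIntervalError(DentageError):
    """Examination date does not lie strictly after the birth date."""


class IncompleteRecordError(DentageError):
    """A stage record is missing a required per-tooth stage."""


class StageLookupError(DentageError):
    """A (tooth, stage) key is absent from a scoring table."""


class ConfigurationError(DentageError):
    """A lookup table, model, or generator configuration is invalid."""


class RankDeficiencyError(DentageError):
    """Too few distinct ages to identify a quadratic fit."""


class UnsupportedCurvatureError(DentageError):
    """Analytic inversion requires a concave (c < 0) calibration curve."""


class InsufficientDataError(DentageError):
    """Not enough observations to compute the requested statistic."""


class OutOfRangeError(DentageError):
    """A chronological age falls outside the supported (6, 15] year range."""


class PartitionError(DentageError):
    """A cohort cell is too small for the requested train/test split."""
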