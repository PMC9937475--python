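"""Exception hierarchy for the lrobserver package."""


class LRObserverError(Exception):
    """Base class for all lrobserver errors."""


class SchemaError(LRObserverError):
    """A required column or config key is missing or malformed."""


class CohortValidationError(LRObserverError):
    """A cohort table row violates an invariant (bad volume, duplicate key...)."""


class IncompleteRecordError(LRObserverError):
    """A subject record lacks a (region, hemisphere) volume a measure needs."""


class StatsParseError(LRObserverError):
    """A FreeSurfer stats file could not be parsed."""


class MissingStructureError(StatsParseError):
    """A required anatomical structure is absent from a stats file."""


class InsufficientDataError(LRObserverError):
    """Too few observations to fit a density or correlation."""


class DegenerateCohortError(LRObserverError):
    """Zero-variance cohort: a Gaussian density cannot be fitted."""


class UndefinedRatioError(LRObserverError):
    """The likelihood ratio is undefined (zero density under a KDE backend)."""


class UnsupportedBackendError(LRObserverError):
    """The operation requires the Gaussian density backend."""


class DegenerateModelError(LRObserverError):
    """Normal and diseased densities coincide: the score is identically zero."""


class UndefinedROCError(LRObserverError):
    """ROC is undefined: only one class present, or an empty test table."""


class UndefinedIntervalError(LRObserverError):
    """A confidence interval cannot be formed from degenerate class counts."""


class ComparabilityError(LRObserverError):
    """Two classification reports do not refer to the same test cohort."""


class ConfigError(LRObserverError):
    """An experiment configuration is invalid or references a missing input."""
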