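"""Exception hierarchy for healthineq."""


class HealthineqError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(HealthineqError, ValueError):
    """An invalid simulation or pipeline configuration."""


class DomainError(HealthineqError, ValueError):
    """An input outside the mathematical domain of an operation."""


class UndefinedIndexError(HealthineqError, ValueError):
    """The concentration index is undefined (zero mean outcome or constant ranks)."""


class OutOfRangeError(HealthineqError, KeyError):
    """A growth-reference lookup outside the tabulated age range."""


class SeparationError(HealthineqError, RuntimeError):
    """Perfect separation detected in a logistic regression."""


class RankDeficiencyError(HealthineqError, ValueError):
    """The design matrix is rank deficient."""
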