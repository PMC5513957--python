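"""Exception types raised across the package."""


class SnarcPowerError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(SnarcPowerError, ValueError):
    """A simulation or grid parameter is outside its valid domain."""


class IncompleteDataError(SnarcPowerError, ValueError):
    """A subject's trial table is missing a hand x magnitude cell."""


class DegenerateRegressionError(SnarcPowerError, ValueError):
    """Too few regression points, or zero variance in the predictor."""


class DegenerateVarianceError(SnarcPowerError, ValueError):
    """A t-test denominator is exactly zero (all slopes identical)."""


class UnbalancedDesignError(SnarcPowerError, ValueError):
    """The factorial ANOVA received unequal cell counts."""
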