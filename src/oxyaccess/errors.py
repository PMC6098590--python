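"""Exception hierarchy for the oxyaccess simulator."""


class OxyAccessError(Exception):
    """Base class for all package errors."""


class InvalidInputError(OxyAccessError, ValueError):
    """A value violates a precondition (negative duration, bad fraction...)."""


class CalibrationError(OxyAccessError, ValueError):
    """Kinetics calibration is impossible for the given anchors."""


class NotCalibratedError(OxyAccessError, RuntimeError):
    """The logistic access model was used before its baseline was calibrated."""


class UnreachableTargetError(OxyAccessError, ValueError):
    """A calibration or search target cannot be attained (e.g. probability 0/1)."""


class UndefinedRatioError(OxyAccessError, ZeroDivisionError):
    """The weekly access ratio is undefined because demand is non-positive."""


class SearchFailureError(OxyAccessError, RuntimeError):
    """The minimal-supply bisection could not bracket the target ratio."""


class ConfigError(OxyAccessError, ValueError):
    """A run configuration failed validation."""
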