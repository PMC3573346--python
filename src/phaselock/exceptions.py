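"""Exception hierarchy shared across the package."""


class PhaselockError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(PhaselockError, ValueError):
    """Raised when an argument violates a documented precondition."""


class UndefinedStatisticError(PhaselockError, ArithmeticError):
    """Raised when a statistic is mathematically undefined for the input (e.g. 0/0)."""


class UndefinedPhaseError(PhaselockError, ArithmeticError):
    """Raised when a phase angle is requested from a zero-magnitude coefficient."""


class EdgeEffectError(PhaselockError, ValueError):
    """Raised when a wavelet evaluation point is too close to a recording edge."""


class UnsupportedMethodError(PhaselockError, TypeError):
    """Raised when an operation needs a p-value a method does not provide directly."""
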