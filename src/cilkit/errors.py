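"""Exception hierarchy shared across the package."""


class CilkitError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(CilkitError, ValueError):
    """Invalid input that violates a documented precondition."""


class DivergenceError(CilkitError, ArithmeticError):
    """A simulation produced non-finite state (blow-up)."""

    def __init__(self, message: str, time: float | None = None):
        super().__init__(message)
        self.time = time


class DomainOverflowError(CilkitError):
    """Mass reached the boundary of the computational domain."""


class UndefinedRadiusError(CilkitError):
    """Quantile radius requested for a zero-mass density."""


class BinsDegenerateError(CilkitError):
    """Too few distinct distances to place the requested number of bins."""


class TimeStepError(CilkitError):
    """Explicit time step violates the stability (CFL) limit."""

    def __init__(self, message: str, suggested_dt: float | None = None):
        super().__init__(message)
        self.suggested_dt = suggested_dt


class GradientFailureError(CilkitError, ArithmeticError):
    """Finite-difference stencil hit a non-finite potential value."""


class ConfigError(CilkitError):
    """Configuration file failed validation; carries all collected messages."""

    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


class PipelineError(CilkitError):
    """A pipeline stage failed; the stage name is part of the message."""
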