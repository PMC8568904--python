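"""Exception hierarchy shared across the package."""


class PmfmError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(PmfmError, ValueError):
    """An argument violates a documented precondition."""


class InfeasibleParametersError(PmfmError, ValueError):
    """Regional parameters violate positivity constraints (w_i or sigma_i <= 0)."""


class DivergenceError(PmfmError, RuntimeError):
    """Numerical integration produced a non-finite or inadmissible state."""

    def __init__(self, message: str, step: int | None = None):
        super().__init__(message)
        self.step = step


class DegenerateSignalError(PmfmError, ValueError):
    """A time course is constant where variance is required."""


class FitFailureError(PmfmError, RuntimeError):
    """Optimization or mixture fitting could not produce a usable result."""
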