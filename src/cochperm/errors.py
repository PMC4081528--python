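"""Exception hierarchy shared by all stages.

The CLI maps these onto exit codes: ValidationError -> 2,
NumericalError (and subclasses) -> 3.
"""


class CochpermError(Exception):
    """Base class for all package errors."""


class ValidationError(CochpermError):
    """Invalid user input or configuration (bad table, non-positive width, ...)."""


class NumericalError(CochpermError):
    """A numerical procedure failed (instability, non-convergence, ...)."""


class CalibrationError(NumericalError):
    """A calibration target is outside the achievable range of the bracket."""

    def __init__(self, message: str, lo_value: float | None = None,
                 hi_value: float | None = None):
        super().__init__(message)
        self.lo_value = lo_value
        self.hi_value = hi_value
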