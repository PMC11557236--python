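"""Exception types shared across the package."""


class PoroidentError(Exception):
    """Base class for all package errors."""


class RangeViolationError(PoroidentError, ValueError):
    """A parameter value lies outside its allowed range.

    Carries the offending parameter name so callers can report which
    coordinate of the parameter space was violated.
    """

    def __init__(self, name: str, value: float, lo: float, hi: float):
        self.name = name
        self.value = value
        self.bounds = (lo, hi)
        super().__init__(
            f"parameter {name!r} = {value!r} outside its range [{lo}, {hi}]"
        )


class InvalidDeformationError(PoroidentError, ValueError):
    """Deformation state with non-positive volume ratio."""


class PoreCollapseError(PoroidentError, ValueError):
    """Volume ratio J <= 1 - phi_w0: the pore space has closed."""


class ConvergenceError(PoroidentError, RuntimeError):
    """A root find or nonlinear solve failed to converge."""
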