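"""Typed errors shared across the package."""


class FvCBError(Exception):
    """Base class for all package errors."""


class ParameterError(FvCBError, ValueError):
    """Invalid biochemical parameter value or unknown parameter key."""


class PoleError(FvCBError, ArithmeticError):
    """A rate equation was evaluated at the pole of its hyperbola."""

    def __init__(self, state, pole):
        self.state = state
        self.pole = pole
        super().__init__(
            f"state {state!s} rate has a pole at C = {pole:g} Pa; "
            "the rate is undefined there"
        )


class DomainError(FvCBError, ValueError):
    """CO2 concentration outside the valid domain of the model."""


class NotAHyperbolaError(FvCBError, ValueError):
    """Conic is not a hyperbola (ellipse/parabola inputs are rejected)."""


class CurveFormatError(FvCBError, ValueError):
    """Malformed gas-exchange curve table."""


class FitError(FvCBError, RuntimeError):
    """Curve fitting could not be set up."""
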