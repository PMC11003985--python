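"""Exception hierarchy shared across the package."""


class WhiskvisError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(WhiskvisError, ValueError):
    """A parameter violates its documented domain (sign, range, shape)."""


class DegenerateNetworkError(WhiskvisError, ArithmeticError):
    """The effective-weight determinant phi is zero; the active-state
    steady state of the rate model is not defined."""


class IntegrationInstabilityError(WhiskvisError, ArithmeticError):
    """Numerical integration produced non-finite population rates."""

    def __init__(self, step: int, time: float):
        self.step = step
        self.time = time
        super().__init__(
            f"non-finite population rate first encountered at integration "
            f"step {step} (t = {time:.6f} s)"
        )


class DegenerateGeometryError(WhiskvisError, ValueError):
    """Geometric input is degenerate (collinear points, zero-length axis)."""


class ConfigError(WhiskvisError, ValueError):
    """A run configuration failed validation; message names the field."""
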