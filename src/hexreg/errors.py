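"""Exception hierarchy for hexreg."""


class HexregError(Exception):
    """Base class for all hexreg errors."""


class FormatError(HexregError):
    """Malformed or unsupported on-disk data."""


class ValidationError(HexregError):
    """Input violates a documented precondition or invariant."""


class MeshError(HexregError):
    """Mesh construction / coarsening / embedding failure."""


class SingularMomentMatrixError(HexregError):
    """MLS moment matrix is singular; the support domain is degenerate
    (e.g. coplanar nodes). Growing the support radius usually fixes it."""


class ElementInversionError(HexregError):
    """An element's deformation gradient has non-positive determinant."""

    def __init__(self, message, element=None):
        super().__init__(message)
        self.element = element


class DivergenceError(HexregError):
    """Explicit integration produced NaN/Inf; reduce the time step."""


class ConvergenceError(HexregError):
    """Equilibrium iteration exceeded max_steps."""

    def __init__(self, message, residual=None):
        super().__init__(message)
        self.residual = residual
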