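"""Exception hierarchy used across the package."""


class PhagospreadError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(PhagospreadError, ValueError):
    """A physical or numerical argument violates a precondition."""


class GeometryError(PhagospreadError, RuntimeError):
    """Contour or mesh is in an invalid state (self-intersection, inversion...)."""


class VolumeDriftError(GeometryError):
    """Enclosed volume drifted too far from the target to be corrected safely."""


class NonConvergenceError(PhagospreadError, RuntimeError):
    """An iterative solver failed to reach its tolerance."""

    def __init__(self, message, residual_history=None):
        super().__init__(message)
        self.residual_history = residual_history if residual_history is not None else []


class FitQualityError(PhagospreadError, RuntimeError):
    """A curve fit did not meet its quality requirements."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
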