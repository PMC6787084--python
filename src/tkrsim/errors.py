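"""Exception hierarchy for the virtual knee test bench."""


class TkrSimError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(TkrSimError, ValueError):
    """Implant/placement parameters violate a geometric invariant."""


class ConfigurationError(TkrSimError, ValueError):
    """A model configuration is inconsistent (unknown bundle, bad table, ...)."""


class ContactInfeasibleError(TkrSimError, RuntimeError):
    """Penetration exceeded the solver guard cap (gross interpenetration)."""

    def __init__(self, max_penetration: float, cap: float):
        self.max_penetration = float(max_penetration)
        self.cap = float(cap)
        super().__init__(
            f"contact penetration {max_penetration:.3f} mm exceeds cap {cap:.3f} mm"
        )


class SolverStepError(TkrSimError, RuntimeError):
    """Newton iteration failed to converge; carries the best iterate found."""

    def __init__(self, message, best_q=None, best_residual=None, iterations=0):
        super().__init__(message)
        self.best_q = best_q
        self.best_residual = best_residual
        self.iterations = iterations


class DegenerateRotationError(TkrSimError, ValueError):
    """Joint-angle decomposition near gimbal lock (|adduction| -> 90 deg)."""


class ComparisonError(TkrSimError, ValueError):
    """Two traces cannot be compared (disjoint flexion ranges, ...)."""
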