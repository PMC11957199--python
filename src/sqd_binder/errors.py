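"""Exception hierarchy."""


class SqdBinderError(Exception):
    """Base class for package errors."""


class FormatError(SqdBinderError):
    """Malformed input file (FCIDUMP / XYZ / manifest)."""


class GeometryError(SqdBinderError):
    """Invalid geometry operation (e.g. coincident translation anchors)."""


class EngineUnavailableError(SqdBinderError):
    """An external electronic-structure engine is required but not installed."""


class CapacityError(SqdBinderError):
    """A determinant space exceeds the configured memory budget."""

    def __init__(self, dimension: int, budget: int):
        self.dimension = dimension
        self.budget = budget
        super().__init__(
            f"determinant space dimension {dimension} exceeds budget {budget}"
        )


class ConvergenceError(SqdBinderError):
    """Iterative eigensolver failed to reach the residual threshold."""

    def __init__(self, message: str, best_residual: float):
        self.best_residual = best_residual
        super().__init__(f"{message} (best residual {best_residual:.3e})")


class InitializationError(SqdBinderError):
    """Occupation initialization found no usable configurations."""
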