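"""Exception hierarchy used across the package."""


class MorphocanvasError(Exception):
    """Base class for all package errors."""


class ParameterError(MorphocanvasError, ValueError):
    """Invalid user-supplied parameter (non-positive size, bad threshold, ...)."""


class GeometryError(MorphocanvasError):
    """Degenerate or invalid geometry (zero-area element, negative volume, ...)."""


class TopologyError(MorphocanvasError):
    """Invalid mesh topology operation (cut path through non-edges, ...)."""


class PlacementError(MorphocanvasError):
    """Could not place the requested number of non-overlapping clones."""

    def __init__(self, requested: int, placed: int):
        self.requested = requested
        self.placed = placed
        super().__init__(
            f"could only place {placed} of {requested} non-overlapping clones"
        )


class ModelError(MorphocanvasError):
    """Invalid model state (non-finite rates, retention out of range, ...)."""


class ConstraintError(MorphocanvasError):
    """Inconsistent displacement constraints."""


class SolverError(MorphocanvasError):
    """Linear solver failed to converge to the requested tolerance."""


class StepSizeError(MorphocanvasError):
    """Time step exceeds the stability bound of the explicit scheme."""


class DomainError(MorphocanvasError, ValueError):
    """Input outside the mathematical domain of an operation."""


class ContractViolation(MorphocanvasError):
    """An interaction hook broke its contract (e.g. moved mesh vertices)."""


class RelaxationError(MorphocanvasError):
    """Incremental strain release failed to reach equilibrium."""

    def __init__(self, message: str, energy_trace=None):
        self.energy_trace = energy_trace
        super().__init__(message)
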