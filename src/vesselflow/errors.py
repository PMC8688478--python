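"""Exception hierarchy for the solver."""


class VesselflowError(Exception):
    """Base class for all package errors."""


class InvalidStateError(VesselflowError):
    """A macroscopic field left its physically admissible range (e.g. rho <= 0)."""


class StabilityError(VesselflowError):
    """The flow violated a stability bound (low-Mach guard, backflow limit)."""


class DivergenceError(VesselflowError):
    """Populations became NaN/Inf during time stepping."""

    def __init__(self, step, message=None):
        self.step = step
        super().__init__(message or f"solver diverged (NaN/Inf populations) at step {step}")


class GeometryError(VesselflowError):
    """Degenerate or inadmissible voxel geometry."""


class TopologyError(GeometryError):
    """Disconnected fluid region or inconsistent wall-link topology."""


class UnboundedDomainError(GeometryError):
    """Fluid touches the lateral bounding box (no containing wall possible)."""


class ConfigError(VesselflowError):
    """Invalid or nonphysical configuration value."""


class ParseError(VesselflowError):
    """Malformed input file."""


class OutOfDomainError(VesselflowError):
    """A sample point lies outside the fluid region."""


class SingularParameterError(VesselflowError):
    """An analytical expression was evaluated at a singular parameter (J0(Lambda) ~ 0)."""
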