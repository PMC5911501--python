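"""Exception hierarchy shared across the package."""


class ValveFsiError(Exception):
    """Base class for all package errors."""


class GeometryError(ValveFsiError):
    """Infeasible geometric parameters or a construction that self-intersects."""


class DegenerateCellError(ValveFsiError):
    """A simplex with non-positive measure (collapsed or inverted)."""


class MeshFormatError(ValveFsiError):
    """Unsupported or malformed mesh file content."""


class ConfigurationError(ValveFsiError):
    """Missing tags, inconsistent sections or invalid values in a run configuration."""


class SolverError(ValveFsiError):
    """Linear or nonlinear solver breakdown."""


class NonConvergenceError(SolverError):
    """Iteration budget exhausted before reaching the requested tolerance.

    Carries ``diagnostics`` (dict) so callers can decide on step rejection.
    """

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class StepRejected(ValveFsiError):
    """A time step could not be completed; the caller should halve dt and retry."""
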