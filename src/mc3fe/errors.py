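"""Exception hierarchy for the virtual mechanical testing pipeline."""


class Mc3feError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(Mc3feError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateFitError(Mc3feError, ValueError):
    """A regression/fit has no unique solution (e.g. zero predictor variance)."""


class DegenerateGeometryError(Mc3feError, ValueError):
    """A geometric operation produced or received an empty/degenerate object."""


class AmbiguousAxisError(Mc3feError, ValueError):
    """Principal-axis fit is ill-posed (near-isotropic point cloud)."""


class InfeasibleAnglesError(Mc3feError, ValueError):
    """Load direction angles are mutually incompatible (sin^2 sum > 1)."""


class InvalidSpecError(Mc3feError, ValueError):
    """A synthetic phantom specification is internally inconsistent."""


class ConstraintDeficiencyError(Mc3feError, RuntimeError):
    """The constrained stiffness system is singular (rigid-body modes remain)."""


class StageError(Mc3feError, RuntimeError):
    """Pipeline stage failure, tagged with stage name and specimen id."""

    def __init__(self, stage: str, specimen: str, cause: BaseException):
        self.stage = stage
        self.specimen = specimen
        self.cause = cause
        super().__init__(f"stage '{stage}' failed for specimen '{specimen}': {cause}")
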