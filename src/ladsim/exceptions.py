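"""Exception hierarchy shared across the package."""


class LadsimError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(LadsimError, ValueError):
    """A physical parameter is outside its allowed range."""


class AnnotationParseError(LadsimError, ValueError):
    """A LAD annotation stream could not be parsed."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class InfeasibleGeometryError(LadsimError, ValueError):
    """The requested chain cannot fit inside the confinement sphere."""


class EscapedBeadError(LadsimError, RuntimeError):
    """A chromatin bead was found outside the confinement sphere."""


class SingularOverlapError(LadsimError, ValueError):
    """Two interacting beads are at zero separation."""


class SingularAngleError(LadsimError, ValueError):
    """Consecutive beads coincide; the bending angle is undefined."""


class UnstableTimestepError(LadsimError, RuntimeError):
    """A bead moved more than half a diameter in one step."""

    def __init__(self, step: int, max_displacement: float):
        self.step = step
        self.max_displacement = max_displacement
        super().__init__(
            f"displacement {max_displacement:.3g} sigma > 0.5 sigma at step {step}; "
            "reduce the timestep"
        )


class CorruptedStateError(LadsimError, RuntimeError):
    """The bond set is inconsistent with the chain eligibility flags."""


class FitFailureError(LadsimError, RuntimeError):
    """A statistical fit (e.g. tangent-correlation decay) did not converge."""


class InvalidInputError(LadsimError, ValueError):
    """An analysis routine received unusable input (e.g. empty trajectory)."""
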