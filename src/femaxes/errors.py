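"""Exception hierarchy."""


class FemaxesError(Exception):
    """Base class for all package errors."""


class MeshError(FemaxesError):
    """Invalid mesh data or an operation precondition on a mesh failed."""


class MeshIOError(FemaxesError):
    """Unreadable or malformed mesh file."""


class DegenerateFitError(FemaxesError):
    """A geometric primitive fit is degenerate (coplanar points, non-ellipse conic, ...)."""


class GenerationError(FemaxesError):
    """The synthetic generator produced an invalid shape for the given parameters."""


class StageError(FemaxesError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
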