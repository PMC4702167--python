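"""Exception hierarchy for the egg-chamber staging toolbox."""


class EggstageError(Exception):
    """Base class for all toolbox errors."""


class DegenerateInputError(EggstageError):
    """Input lacks the structure an operation needs (constant image,
    collinear points, empty mask, ...)."""


class SegmentationError(EggstageError):
    """A pipeline stage failed; ``stage`` names the failing step."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


class FitError(EggstageError):
    """A statistical model could not be fitted on the given data."""
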