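"""Exception hierarchy shared across the package."""


class FosmidScreenError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(FosmidScreenError, ValueError):
    """A parameter violates its documented constraints."""


class DataError(FosmidScreenError, ValueError):
    """Input data are malformed (bad characters, non-finite values, ...)."""


class ConsistencyError(FosmidScreenError, ValueError):
    """Two inputs that must agree do not (e.g. design references unknown clone)."""


class InsufficientDataError(FosmidScreenError, ValueError):
    """Not enough observations to compute the requested statistic."""


class PipelineError(FosmidScreenError, RuntimeError):
    """A pipeline stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause
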