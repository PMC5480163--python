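"""Exception types shared across the pipeline stages."""


class CentsatError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(CentsatError, ValueError):
    """A simulation or run specification violates its invariants."""


class EmptyInputError(CentsatError, ValueError):
    """An operation received an empty read set or genome."""


class ShortfallError(CentsatError, ValueError):
    """Fewer reads available than a sampling operation requires."""

    def __init__(self, needed: int, available: int):
        self.needed = needed
        self.available = available
        super().__init__(
            f"need {needed} reads but only {available} available "
            f"(deficit {needed - available})"
        )


class ConsensusError(CentsatError, ValueError):
    """Consensus refinement could not proceed (e.g. no aligning reads)."""


class UndefinedComparisonError(CentsatError, ValueError):
    """A distribution comparison is undefined (zero hits on one side)."""


class IncomparableTracksError(CentsatError, ValueError):
    """Two enrichment tracks share no usable bins in the requested window."""


class StageError(CentsatError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
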