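"""Exception hierarchy."""


class LifetabError(Exception):
    """Base class for all package errors."""


class ScheduleValidationError(LifetabError, ValueError):
    """An input mortality or prevalence schedule violates its invariants."""


class ExtensionFitError(LifetabError, RuntimeError):
    """An old-age extension family failed to fit or no family converged."""


class PrevalenceCoverageError(LifetabError, ValueError):
    """A prevalence schedule does not cover the requested ages."""


class StageError(LifetabError, RuntimeError):
    """A pipeline stage failed; carries the stage name and offending group."""

    def __init__(self, stage: str, group: str, message: str):
        self.stage = stage
        self.group = group
        super().__init__(f"stage {stage!r} failed for group {group!r}: {message}")
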