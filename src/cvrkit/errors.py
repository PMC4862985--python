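"""Exception hierarchy shared across the toolkit.

Everything derives from :class:`CvrError` so callers can catch one base
class at pipeline level; argument-validation errors also derive from
:class:`ValueError` to behave like ordinary Python misuse.
"""


class CvrError(Exception):
    """Base class for all cvrkit errors."""


class InvalidArgumentError(CvrError, ValueError):
    """An argument violates a documented precondition."""


class DetectionError(CvrError):
    """Breath segmentation / end-tidal detection failed (e.g. flat trace)."""


class QcError(CvrError):
    """Quality-control constraints violated (too few volumes, censor budget)."""


class GridMismatchError(CvrError):
    """Two images/masks do not share the same spatial grid."""


class InsufficientDataError(CvrError):
    """Not enough observations for the requested statistic."""


class UndefinedStatisticError(CvrError):
    """The statistic is undefined on this input (e.g. zero variance)."""


class UnsupportedSampleSizeError(InvalidArgumentError):
    """Sample size outside the supported range of the test."""


class DesignError(CvrError):
    """Rank-deficient or otherwise degenerate model design matrix."""


class SpecError(CvrError, ValueError):
    """A simulation specification is internally inconsistent."""


class ParamsError(CvrError, ValueError):
    """Cohort-generator parameters are infeasible."""


class PipelineError(CvrError):
    """A pipeline stage failed; carries stage and subject context."""

    def __init__(self, stage: str, subject: str | None, cause: BaseException):
        self.stage = stage
        self.subject = subject
        self.cause = cause
        where = f"stage '{stage}'" + (f", subject '{subject}'" if subject else "")
        super().__init__(f"pipeline failed at {where}: {cause}")
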