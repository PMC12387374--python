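"""Exception hierarchy for infoseason.

All errors raised by the package derive from :class:`InfoseasonError` so
callers can catch the package's failures with a single except clause while
still distinguishing format problems from statistical degeneracies.
"""


class InfoseasonError(Exception):
    """Base class for all infoseason errors."""


class FormatError(InfoseasonError, ValueError):
    """Malformed input: bad CSV dialect, out-of-range value, non-numeric cell."""


class GapError(FormatError):
    """A calendar month is missing or duplicated in a monthly series."""


class SeriesLengthError(InfoseasonError, ValueError):
    """Series too short for the requested operation (minimum 24 months)."""


class DomainError(InfoseasonError, ValueError):
    """Argument outside its mathematical domain (p-value, month index, ...)."""


class RankError(InfoseasonError, ValueError):
    """Design matrix is rank deficient (too few distinct phases)."""


class DegreesOfFreedomError(InfoseasonError, ValueError):
    """No residual degrees of freedom left for inference."""


class PerfectFitError(InfoseasonError, ValueError):
    """An operation that needs SSE > 0 (e.g. ln SSE) met a zero-residual fit."""


class PipelineStageError(InfoseasonError, RuntimeError):
    """Wraps a failure inside the pipeline with its stage and location id."""

    def __init__(self, stage: str, location_id: str, cause: Exception):
        self.stage = stage
        self.location_id = location_id
        self.cause = cause
        super().__init__(f"stage {stage!r} failed for location {location_id!r}: {cause}")
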