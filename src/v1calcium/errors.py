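"""Exception hierarchy shared across the pipeline."""


class V1CalciumError(Exception):
    """Base class for all pipeline errors."""


class InvalidArgumentError(V1CalciumError, ValueError):
    """An argument violates a precondition (wrong sign, length mismatch...)."""


class DegenerateBaselineError(V1CalciumError):
    """F0 is non-positive at one or more frames; dF/F0 is undefined there."""

    def __init__(self, frames):
        self.frames = frames
        super().__init__(
            f"baseline F0 <= 0 at {len(frames)} frame(s), first offenders: "
            f"{list(frames[:5])}"
        )


class DegenerateTraceError(V1CalciumError):
    """A trace has zero variance where variation is required."""


class DegenerateTuningError(V1CalciumError):
    """Tuning statistics are undefined (flat or all-zero response vector)."""


class StateMissingError(V1CalciumError):
    """A behavioral state has no frames; per-state statistics are undefined."""


class InsufficientDataError(V1CalciumError):
    """Too few neurons, trials, or conditions for the requested statistic."""


class InvalidScheduleError(V1CalciumError):
    """A trial window falls outside the recording or speed trace."""


class UndefinedCCOMError(V1CalciumError):
    """All contrast-response weights are <= 0; the center of mass is undefined."""


class EmptyTracingError(V1CalciumError):
    """The traced-cell table contains no input cells."""


class SchemaError(V1CalciumError):
    """A session container is missing a required group or has a bad version."""


class NotInterpolatableError(V1CalciumError):
    """A blink gap covers the entire trace; nothing remains to fit a spline."""
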