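"""Exception hierarchy.

Every error carries a ``stage`` tag naming the pipeline stage it came from,
so command-line wrappers can map failures to distinct exit codes.
"""


class AffectDynError(Exception):
    """Base class for all package errors."""

    stage = "general"


class InvalidInputError(AffectDynError):
    """Malformed domain input (out-of-range rating, bad config value)."""

    stage = "input"


class ParseError(AffectDynError):
    """A file could not be parsed; ``line`` is 1-based where applicable."""

    stage = "parse"

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class PoolExhaustedError(AffectDynError):
    """An image pool is too small for the blocks that draw from it."""

    stage = "schedule"

    def __init__(self, state: str, needed: int, available: int):
        self.state = state
        super().__init__(
            f"image pool for state {state} has {available} images, {needed} needed"
        )


class OverlappingWindowsError(AffectDynError):
    stage = "windowing"


class InsufficientBeatsError(AffectDynError):
    stage = "signal"


class UncorrectableSeriesError(AffectDynError):
    stage = "correction"


class SparseWindowError(AffectDynError):
    """An analysis window holds fewer intervals than required."""

    stage = "windowing"

    def __init__(self, from_state: str, to_state: str, n_found: int, n_required: int):
        self.window = (from_state, to_state)
        super().__init__(
            f"window {from_state}->{to_state} holds {n_found} intervals, "
            f"{n_required} required"
        )


class DegenerateRowError(AffectDynError):
    """A row of the RMSSD matrix sums to zero and cannot be normalized."""

    stage = "markov"

    def __init__(self, state: str):
        self.state = state
        super().__init__(f"row {state} of the RMSSD matrix has zero sum")


class NonUniqueSteadyStateError(AffectDynError):
    """The chain is reducible or periodic: no unique stationary distribution."""

    stage = "markov"


class InvalidConfigError(AffectDynError):
    stage = "config"
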