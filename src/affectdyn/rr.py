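"""RR-interval series: I/O, artifact correction, RMSSD and heart-rate summaries.

RMSSD (root mean square of successive differences) is the time-domain
heart-rate-variability index used throughout:

    RMSSD = sqrt( (1 / (N - 1)) * sum_{i=1}^{N-1} (RR_{i+1} - RR_i)^2 )

with RR_i the i-th beat-to-beat interval in milliseconds and N the number of
intervals analyzed.  It mainly reflects vagally mediated (parasympathetic)
variability and remains valid on ultra-short windows down to ~10-30 s, which
is what the windowed analysis here relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    InsufficientBeatsError,
    InvalidInputError,
    ParseError,
    SparseWindowError,
    UncorrectableSeriesError,
)
from .protocol import WindowSet

#: Artifact-detection threshold (ms deviation from the local median) per level.
CORRECTION_THRESHOLDS_MS = {
    "very_low": 450.0,
    "low": 350.0,
    "medium": 250.0,
    "strong": 150.0,
    "very_strong": 50.0,
}

CORRECTION_LEVELS = ("none",) + tuple(CORRECTION_THRESHOLDS_MS)


@dataclass
class RRSeries:
    """An ordered series of RR intervals (ms) with derived beat times.

    ``beat_times_s[i]`` is the time of the beat terminating interval ``i``,
    i.e. the cumulative sum of intervals, in recording time.
    ``origin_offset_s`` places recording time on the protocol clock: protocol
    time of beat ``i`` is ``origin_offset_s + beat_times_s[i]``.
    """

    intervals_ms: np.ndarray
    origin_offset_s: float = 0.0
    beat_times_s: np.ndarray = field(init=False)

    def __post_init__(self):
        self.intervals_ms = np.asarray(self.intervals_ms, dtype=float)
        if self.intervals_ms.ndim != 1 or len(self.intervals_ms) == 0:
            raise InvalidInputError("RR series must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(self.intervals_ms)) or np.any(self.intervals_ms <= 0):
            raise InvalidInputError("RR intervals must be positive and finite")
        self.beat_times_s = np.cumsum(self.intervals_ms) / 1000.0

    def __len__(self) -> int:
        return len(self.intervals_ms)

    @property
    def duration_s(self) -> float:
        return float(self.beat_times_s[-1])

    def protocol_times_s(self) -> np.ndarray:
        return self.origin_offset_s + self.beat_times_s

    def to_plain(self, path) -> None:
        """Write the plain format: one interval in ms per line."""
        with open(path, "w") as fh:
            for v in self.intervals_ms:
                fh.write(f"{v:.6g}\n")


@dataclass
class ArtifactReport:
    n_flagged: int
    flagged_indices: list[int]
    correction_level: str
    threshold_ms: float | None

    def to_dict(self) -> dict:
        return {
            "n_flagged": self.n_flagged,
            "flagged_indices": list(self.flagged_indices),
            "correction_level": self.correction_level,
            "threshold_ms": self.threshold_ms,
        }


def read_rr(path, format: str = "plain", origin_offset_s: float = 0.0) -> RRSeries:
    """Read an RR recording.

    ``plain``: one interval (ms) per line.  ``timed_csv``: two comma-separated
    columns ``beat_time_s,rr_ms`` with a header line; beat times are taken
    from the file only for validation, intervals are authoritative.
    """
    if format not in ("plain", "timed_csv"):
        raise InvalidInputError(f"unknown RR format {format!r}")
    intervals = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    for lineno, raw in enumerate(lines, start=1):
        if format == "timed_csv" and lineno == 1:
            continue  # header
        text = raw.strip()
        if not text:
            continue
        if format == "timed_csv":
            parts = text.split(",")
            if len(parts) != 2:
                raise ParseError("expected 'beat_time_s,rr_ms'", line=lineno)
            text = parts[1].strip()
        try:
            value = float(text)
        except ValueError as exc:
            raise ParseError(f"non-numeric RR interval {text!r}", line=lineno) from exc
        if value <= 0:
            raise ParseError(f"non-positive RR interval {value}", line=lineno)
        intervals.append(value)
    if not intervals:
        raise ParseError("empty RR recording")
    return RRSeries(np.array(intervals), origin_offset_s=origin_offset_s)


def _local_medians(
    x: np.ndarray, exclude: np.ndarray | None = None, half_window: int = 5
) -> np.ndarray:
    """Median of the 11-beat neighborhood of each interval, excluding itself.

    Indices in ``exclude`` are left out of every neighborhood (unless that
    would empty it), so already-suspect beats do not contaminate the local
    reference rhythm.
    """
    n = len(x)
    medians = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half_window), min(n, i + half_window + 1)
        idx = np.arange(lo, hi)
        idx = idx[idx != i]
        if exclude is not None:
            clean = idx[~exclude[idx]]
            if len(clean) > 0:
                idx = clean
        medians[i] = np.median(x[idx])
    return medians


def _flag_artifacts(x: np.ndarray, threshold: float) -> np.ndarray:
    """Threshold rule with a self-decontaminating local median.

    A burst of adjacent artifacts drags the plain local median toward the
    artifact values, hiding part of the burst; re-estimating the median over
    currently-unflagged neighbors until the flag set stabilizes recovers the
    whole burst.
    """
    flagged = np.zeros(len(x), dtype=bool)
    for _ in range(10):
        new = np.abs(x - _local_medians(x, exclude=flagged)) > threshold
        if np.array_equal(new, flagged):
            break
        flagged = new
    return flagged


def correct_artifacts(rr: RRSeries, level: str) -> tuple[RRSeries, ArtifactReport]:
    """Flag and repair ectopic/missed-beat artifacts by a threshold rule.

    An interval is flagged when it deviates from the median of its 11-beat
    neighborhood (itself excluded) by more than the level's threshold:
    very_low 450 ms, low 350, medium 250, strong 150, very_strong 50.

    Each maximal run of flagged intervals is replaced by intervals linearly
    interpolated between the nearest unflagged neighbors, re-dividing the
    run's exact time span into the number of beats the local rhythm implies.
    The underlying ECG time is fixed, so correction must not move the beats
    that follow: an ectopic split (two short intervals) collapses back to
    one normal interval and a missed beat (one double-length interval)
    splits into two, leaving every unflagged beat's absolute time — and the
    recording's total duration — unchanged.  Unflagged intervals are
    returned bit-identical.  ``level="none"`` is the identity.
    """
    if level == "none":
        report = ArtifactReport(0, [], "none", None)
        return RRSeries(rr.intervals_ms.copy(), rr.origin_offset_s), report
    if level not in CORRECTION_THRESHOLDS_MS:
        raise InvalidInputError(
            f"unknown correction level {level!r}; choose from {CORRECTION_LEVELS}"
        )
    if len(rr) < 5:
        raise InsufficientBeatsError("artifact correction needs at least 5 intervals")

    threshold = CORRECTION_THRESHOLDS_MS[level]
    x = rr.intervals_ms.copy()
    report = None
    # A burst of adjacent artifacts contaminates its own local median, so a
    # single flag-and-repair pass can miss part of the burst; iterate to a
    # fixed point (makes the operation idempotent by construction).
    for _ in range(20):
        flagged = _flag_artifacts(x, threshold)
        if report is None:
            if flagged.all():
                raise UncorrectableSeriesError("every interval flagged as artifact")
            report = ArtifactReport(
                n_flagged=int(flagged.sum()),
                flagged_indices=np.flatnonzero(flagged).tolist(),
                correction_level=level,
                threshold_ms=threshold,
            )
        if not flagged.any():
            break
        x = _repair_flagged_runs(x, flagged)
    return RRSeries(x, rr.origin_offset_s), report


def _repair_flagged_runs(x: np.ndarray, flagged: np.ndarray) -> np.ndarray:
    """Replace each maximal flagged run, preserving its exact time span."""
    n = len(x)
    out: list[float] = []
    i = 0
    while i < n:
        if not flagged[i]:
            out.append(float(x[i]))
            i += 1
            continue
        j = i
        while j < n and flagged[j]:
            j += 1
        span_ms = float(x[i:j].sum())
        left = float(x[i - 1]) if i > 0 else None
        right = float(x[j]) if j < n else None
        local = float(np.mean([v for v in (left, right) if v is not None]))
        k = max(1, int(round(span_ms / local)))
        lo = left if left is not None else right
        hi = right if right is not None else left
        ramp = lo + (hi - lo) * np.arange(1, k + 1) / (k + 1)
        out.extend((ramp * (span_ms / ramp.sum())).tolist())
        i = j
    return np.array(out)


def rmssd(intervals_ms) -> float:
    """Root mean square of successive differences, in ms."""
    x = np.asarray(intervals_ms, dtype=float)
    if len(x) < 2:
        raise InsufficientBeatsError("RMSSD needs at least 2 intervals")
    d = np.diff(x)
    return float(np.sqrt(np.mean(d * d)))


def mean_hr(intervals_ms) -> tuple[float, float]:
    """Mean heart rate (bpm) and the equivalent mean RR (ms, = 60000/HR)."""
    x = np.asarray(intervals_ms, dtype=float)
    if len(x) == 0:
        raise InsufficientBeatsError("mean HR needs at least 1 interval")
    rr_mean = float(np.mean(x))
    return 60000.0 / rr_mean, rr_mean


def windowed_rmssd(rr: RRSeries, windows: WindowSet, min_intervals: int = 3):
    """RMSSD per analysis window, arranged as a 4x4 matrix.

    An interval belongs to a window when its terminating beat's protocol time
    falls in the half-open span ``[t_start_s, t_end_s)`` — half-open so a
    beat on a shared boundary is counted once.  Windows with fewer than
    ``min_intervals`` intervals raise :class:`SparseWindowError`.
    """
    from .markov import RMSSDMatrix  # local import: avoid a cycle

    windows.validate()
    times = rr.protocol_times_s()
    values = np.full((4, 4), np.nan)
    order = "ABCD"
    for w in windows:
        mask = (times >= w.t_start_s) & (times < w.t_end_s)
        n = int(mask.sum())
        if n < min_intervals:
            raise SparseWindowError(w.from_state, w.to_state, n, min_intervals)
        values[order.index(w.from_state), order.index(w.to_state)] = rmssd(
            rr.intervals_ms[mask]
        )
    return RMSSDMatrix(values)
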