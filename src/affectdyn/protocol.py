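"""Circumplex state space and block-design experimental protocol.

Affective states are the four quadrants of the circumplex model of affect
(valence x arousal): stress (A: high arousal, negative valence), engagement
(B: high arousal, positive), boredom (C: low arousal, negative) and
relaxation (D: low arousal, positive).

The protocol presents 13 two-minute blocks of affective images such that the
12 block boundaries realize each of the 12 distinct ordered transitions
between the four states exactly once — an Eulerian circuit on the complete
directed graph K4*.  Short-term heart-rate variability is then read off 16
thirty-second analysis windows: one straddling each block boundary (the 12
transition windows) and one inside the first block of each state (the 4
self-transition windows).
"""

from __future__ import annotations

import csv
import json
import random
from dataclasses import dataclass, field

from .errors import (
    InvalidInputError,
    OverlappingWindowsError,
    ParseError,
    PoolExhaustedError,
)

#: Sentinel returned by :func:`classify_stimulus` for ratings in the dead zone.
EXCLUDED = "EXCLUDED"

STATE_LABELS = ("A", "B", "C", "D")


@dataclass(frozen=True)
class AffectState:
    """One circumplex quadrant.

    The letter-to-polarity mapping is fixed: A and B are high arousal,
    C and D low arousal; A and C are negative valence, B and D positive.
    """

    label: str
    arousal: str  # "high" | "low"
    valence: str  # "negative" | "positive"
    name: str


STATES = {
    "A": AffectState("A", "high", "negative", "stress"),
    "B": AffectState("B", "high", "positive", "engagement"),
    "C": AffectState("C", "low", "negative", "boredom"),
    "D": AffectState("D", "low", "positive", "relaxation"),
}


@dataclass(frozen=True)
class StimulusRating:
    """Normative valence/arousal means for one image on the 9-point SAM scale."""

    image_id: str
    valence_mean: float
    arousal_mean: float

    def __post_init__(self):
        for attr in ("valence_mean", "arousal_mean"):
            v = getattr(self, attr)
            if not (1.0 <= v <= 9.0):
                raise InvalidInputError(
                    f"{attr}={v} for image {self.image_id!r} outside the SAM range [1, 9]"
                )


def classify_stimulus(
    rating: StimulusRating, high_cut: float = 6.0, low_cut: float = 4.0
) -> str:
    """Map a rated image to a circumplex quadrant, or EXCLUDED.

    An image belongs to a quadrant only when both dimensions are polarized:
    strictly above ``high_cut`` or strictly below ``low_cut``.  Ratings with
    either dimension inside ``[low_cut, high_cut]`` (the ambiguous middle of
    the scale, cut values included) are excluded from the stimulus set.
    """
    if not low_cut < high_cut:
        raise InvalidInputError("low_cut must be smaller than high_cut")

    def polarity(v: float) -> str | None:
        if v > high_cut:
            return "high"
        if v < low_cut:
            return "low"
        return None

    ar = polarity(rating.arousal_mean)
    va = polarity(rating.valence_mean)
    if ar is None or va is None:
        return EXCLUDED
    valence = "positive" if va == "high" else "negative"
    for state in STATES.values():
        if state.arousal == ar and state.valence == valence:
            return state.label
    raise AssertionError("unreachable: quadrants cover all polarized ratings")


@dataclass
class BlockSchedule:
    """The 13-block stimulus timeline.

    ``states`` lists the quadrant of each block in presentation order; the 12
    consecutive ordered pairs are exactly the 12 distinct directed transitions.
    Times inside the object are relative to the onset of the first stimulus
    image; the pre/post baselines sit outside that origin.
    """

    states: list[str]
    block_duration_s: float = 120.0
    images_per_block: int = 12
    image_duration_s: float = 10.0
    baseline_pre_s: float = 120.0
    baseline_post_s: float = 120.0
    image_assignment: dict[int, list[str]] | None = None

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if len(self.states) != 13:
            raise InvalidInputError(f"schedule needs 13 blocks, got {len(self.states)}")
        unknown = set(self.states) - set(STATE_LABELS)
        if unknown:
            raise InvalidInputError(f"unknown state labels: {sorted(unknown)}")
        pairs = list(zip(self.states, self.states[1:]))
        expected = {(i, j) for i in STATE_LABELS for j in STATE_LABELS if i != j}
        if len(pairs) != len(set(pairs)) or set(pairs) != expected:
            raise InvalidInputError(
                "block sequence must realize each of the 12 distinct ordered "
                "transitions exactly once"
            )
        if self.images_per_block * self.image_duration_s != self.block_duration_s:
            raise InvalidInputError(
                "images_per_block * image_duration_s must equal block_duration_s"
            )

    @property
    def n_blocks(self) -> int:
        return len(self.states)

    @property
    def total_stimulus_s(self) -> float:
        return self.n_blocks * self.block_duration_s

    def block_start_s(self, index: int) -> float:
        return index * self.block_duration_s

    def first_block_of(self, state: str) -> int:
        return self.states.index(state)

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        blocks = []
        for i, s in enumerate(self.states):
            block = {"index": i, "state": s, "t_start_s": self.block_start_s(i)}
            if self.image_assignment is not None:
                block["images"] = list(self.image_assignment[i])
            blocks.append(block)
        return {
            "states": list(self.states),
            "block_duration_s": self.block_duration_s,
            "images_per_block": self.images_per_block,
            "image_duration_s": self.image_duration_s,
            "baseline_pre_s": self.baseline_pre_s,
            "baseline_post_s": self.baseline_post_s,
            "blocks": blocks,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_dict(cls, d: dict) -> "BlockSchedule":
        assignment = None
        if d.get("blocks") and "images" in d["blocks"][0]:
            assignment = {b["index"]: list(b["images"]) for b in d["blocks"]}
        return cls(
            states=list(d["states"]),
            block_duration_s=d.get("block_duration_s", 120.0),
            images_per_block=d.get("images_per_block", 12),
            image_duration_s=d.get("image_duration_s", 10.0),
            baseline_pre_s=d.get("baseline_pre_s", 120.0),
            baseline_post_s=d.get("baseline_post_s", 120.0),
            image_assignment=assignment,
        )

    @classmethod
    def from_json(cls, path) -> "BlockSchedule":
        with open(path) as fh:
            try:
                d = json.load(fh)
            except json.JSONDecodeError as exc:
                raise ParseError(f"invalid schedule JSON: {exc}") from exc
        return cls.from_dict(d)


@dataclass(frozen=True)
class AnalysisWindow:
    """A 30-second RMSSD window attributed to one directed transition."""

    from_state: str
    to_state: str
    t_start_s: float
    t_end_s: float

    @property
    def kind(self) -> str:
        return "self" if self.from_state == self.to_state else "transition"

    @property
    def width_s(self) -> float:
        return self.t_end_s - self.t_start_s


@dataclass
class WindowSet:
    """The 16 analysis windows of one protocol run, one per matrix cell."""

    windows: list[AnalysisWindow] = field(default_factory=list)

    def __iter__(self):
        return iter(self.windows)

    def __len__(self):
        return len(self.windows)

    def by_kind(self, kind: str) -> list[AnalysisWindow]:
        return [w for w in self.windows if w.kind == kind]

    def validate(self) -> None:
        if len(self.windows) != 16:
            raise InvalidInputError(f"expected 16 windows, got {len(self.windows)}")
        cells = {(w.from_state, w.to_state) for w in self.windows}
        if len(cells) != 16:
            raise InvalidInputError("window (from, to) labels must tile the 4x4 matrix")
        trans = sorted(self.by_kind("transition"), key=lambda w: w.t_start_s)
        for a, b in zip(trans, trans[1:]):
            if b.t_start_s < a.t_end_s:
                raise OverlappingWindowsError(
                    f"transition windows [{a.t_start_s}, {a.t_end_s}) and "
                    f"[{b.t_start_s}, {b.t_end_s}) overlap"
                )

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["from_state", "to_state", "kind", "t_start_s", "t_end_s"])
            for w in sorted(self.windows, key=lambda w: w.t_start_s):
                writer.writerow([w.from_state, w.to_state, w.kind, w.t_start_s, w.t_end_s])


def generate_schedule(seed: int) -> BlockSchedule:
    """Draw a random valid block order covering all 12 directed transitions.

    Uses a randomized Hierholzer traversal of the complete directed graph on
    the four states (every node has in-degree = out-degree = 3, so an
    Eulerian circuit always exists).  Deterministic for a given ``seed``;
    different seeds sample different circuits.
    """
    rng = random.Random(seed)
    start = rng.choice(STATE_LABELS)
    remaining = {
        s: rng.sample([t for t in STATE_LABELS if t != s], 3) for s in STATE_LABELS
    }

    # Hierholzer: walk until stuck (necessarily back at the start node),
    # then splice in detours from nodes with unused edges.
    circuit = [start]
    stack = [start]
    path = []
    while stack:
        node = stack[-1]
        if remaining[node]:
            stack.append(remaining[node].pop())
        else:
            path.append(stack.pop())
    circuit = path[::-1]
    return BlockSchedule(states=circuit)


def assign_images(
    schedule: BlockSchedule,
    assignments: dict[str, list[str]],
    seed: int,
) -> BlockSchedule:
    """Attach a unique random image sequence to every block.

    Each block draws ``images_per_block`` images without replacement from its
    state's pool; no image is reused anywhere in the run.
    """
    rng = random.Random(seed)
    pools = {}
    for state in STATE_LABELS:
        pool = list(assignments.get(state, []))
        needed = schedule.images_per_block * schedule.states.count(state)
        if len(pool) < needed:
            raise PoolExhaustedError(state, needed, len(pool))
        rng.shuffle(pool)
        pools[state] = pool
    assignment = {}
    for i, state in enumerate(schedule.states):
        assignment[i] = [pools[state].pop() for _ in range(schedule.images_per_block)]
    return BlockSchedule(
        states=list(schedule.states),
        block_duration_s=schedule.block_duration_s,
        images_per_block=schedule.images_per_block,
        image_duration_s=schedule.image_duration_s,
        baseline_pre_s=schedule.baseline_pre_s,
        baseline_post_s=schedule.baseline_post_s,
        image_assignment=assignment,
    )


def place_windows(
    schedule: BlockSchedule,
    half_width_s: float = 15.0,
    self_center_s: float = 60.0,
) -> WindowSet:
    """Place the 16 analysis windows on the protocol timeline.

    Transition windows straddle each of the 12 block boundaries
    (``120k +/- 15`` s for boundary ``k``); the self window of each state sits
    at the middle of that state's first block (``block start + 60 +/- 15`` s).
    Times are relative to first-stimulus onset.
    """
    if half_width_s >= schedule.block_duration_s / 2:
        raise OverlappingWindowsError(
            f"half_width_s={half_width_s} makes adjacent transition windows overlap"
        )
    windows = []
    for k in range(1, schedule.n_blocks):
        boundary = k * schedule.block_duration_s
        windows.append(
            AnalysisWindow(
                from_state=schedule.states[k - 1],
                to_state=schedule.states[k],
                t_start_s=boundary - half_width_s,
                t_end_s=boundary + half_width_s,
            )
        )
    for state in STATE_LABELS:
        start = schedule.block_start_s(schedule.first_block_of(state))
        windows.append(
            AnalysisWindow(
                from_state=state,
                to_state=state,
                t_start_s=start + self_center_s - half_width_s,
                t_end_s=start + self_center_s + half_width_s,
            )
        )
    ws = WindowSet(windows)
    ws.validate()
    return ws


def read_ratings_csv(path) -> list[StimulusRating]:
    """Read a ratings table: header ``image_id,valence_mean,arousal_mean``."""
    ratings = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"image_id", "valence_mean", "arousal_mean"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ParseError(f"ratings CSV must have columns {sorted(required)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                ratings.append(
                    StimulusRating(
                        image_id=row["image_id"],
                        valence_mean=float(row["valence_mean"]),
                        arousal_mean=float(row["arousal_mean"]),
                    )
                )
            except (TypeError, ValueError) as exc:
                raise ParseError(f"bad rating row: {exc}", line=lineno) from exc
    return ratings
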