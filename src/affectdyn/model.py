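"""Model/results objects tying the pipeline together.

:class:`AffectDynamics` is built from an RR recording and a block schedule;
``fit()`` runs artifact correction, windowed RMSSD, Markovization, the
grouped descriptive indexes and both steady-state methods, returning an
:class:`AffectDynamicsResults` that renders a summary table and serializes a
machine-readable report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import __version__ as _pkg_version
from .graph import export_graph
from .markov import (
    MarkovIndexes,
    RMSSDMatrix,
    STATE_ORDER,
    SteadyStateResult,
    TransitionMatrix,
    grouped_indexes,
    markovize,
    steady_state_eigen,
    steady_state_power,
    uniform_initial,
)
from .protocol import BlockSchedule, WindowSet, place_windows
from .rr import ArtifactReport, RRSeries, correct_artifacts, read_rr, windowed_rmssd


class AffectDynamics:
    """Affect-dynamics model for one subject's protocol run.

    Parameters
    ----------
    rr : RRSeries
        The RR recording, aligned to the protocol clock via its
        ``origin_offset_s`` (0 means recording starts at first-stimulus
        onset).
    schedule : BlockSchedule
        The 13-block timeline the recording was acquired under.
    correction_level : str
        Artifact-correction threshold level ("none", "very_low", "low",
        "medium", "strong", "very_strong").
    min_intervals : int
        Minimum intervals per analysis window; windows below it are an error
        rather than a silently unstable RMSSD.
    """

    def __init__(
        self,
        rr: RRSeries,
        schedule: BlockSchedule,
        correction_level: str = "medium",
        min_intervals: int = 3,
        half_width_s: float = 15.0,
        self_center_s: float = 60.0,
    ):
        self.rr = rr
        self.schedule = schedule
        self.correction_level = correction_level
        self.min_intervals = min_intervals
        self.windows: WindowSet = place_windows(
            schedule, half_width_s=half_width_s, self_center_s=self_center_s
        )
        self.provenance: dict = {}

    @classmethod
    def from_files(
        cls,
        rr_path,
        schedule_path,
        rr_format: str = "plain",
        protocol_start_s: float = 0.0,
        **kwargs,
    ) -> "AffectDynamics":
        """Build the model from an RR recording file and a schedule JSON.

        ``protocol_start_s`` is the recording time at which the first
        stimulus appeared; beats before it are shifted to negative protocol
        times and fall outside every window.
        """
        rr = read_rr(rr_path, format=rr_format, origin_offset_s=-protocol_start_s)
        schedule = BlockSchedule.from_json(schedule_path)
        model = cls(rr, schedule, **kwargs)
        model.provenance = {
            "rr_path": str(rr_path),
            "schedule_path": str(schedule_path),
            "rr_format": rr_format,
            "protocol_start_s": protocol_start_s,
        }
        return model

    def fit(
        self, steps: int = 10, tol: float = 1e-8, renormalize_steady: bool = False
    ) -> "AffectDynamicsResults":
        corrected, artifact_report = correct_artifacts(self.rr, self.correction_level)
        rmssd_matrix = windowed_rmssd(
            corrected, self.windows, min_intervals=self.min_intervals
        )
        P = markovize(rmssd_matrix)
        indexes = grouped_indexes(P)
        steady_power = steady_state_power(
            P, uniform_initial(), steps=steps, tol=tol, renormalize=renormalize_steady
        )
        steady_eigen = steady_state_eigen(P)
        return AffectDynamicsResults(
            model=self,
            rmssd_matrix=rmssd_matrix,
            transition_matrix=P,
            indexes=indexes,
            steady_power=steady_power,
            steady_eigen=steady_eigen,
            artifact_report=artifact_report,
        )


@dataclass
class AffectDynamicsResults:
    """Fitted quantities: matrices, grouped indexes and steady states."""

    model: AffectDynamics
    rmssd_matrix: RMSSDMatrix
    transition_matrix: TransitionMatrix
    indexes: MarkovIndexes
    steady_power: SteadyStateResult
    steady_eigen: SteadyStateResult
    artifact_report: ArtifactReport

    def summary(self) -> str:
        """Plain-text summary in the style of a regression results table."""
        P = self.transition_matrix
        lines = []
        add = lines.append
        add("Affect Dynamics (discrete-time Markov chain over circumplex states)")
        add("=" * 68)
        add(f"Beats analyzed: {len(self.model.rr):>6d}    "
            f"Artifacts corrected: {self.artifact_report.n_flagged} "
            f"(level={self.artifact_report.correction_level})")
        add("")
        add("Windowed RMSSD (ms)            Transition probabilities")
        hdr = "      " + "".join(f"{s:>7}" for s in STATE_ORDER)
        add(hdr + "    " + hdr)
        for i, s in enumerate(STATE_ORDER):
            raw = "".join(f"{self.rmssd_matrix.values[i, j]:7.1f}" for j in range(4))
            prob = "".join(f"{P.values[i, j]:7.2f}" for j in range(4))
            add(f"  {s}   {raw}      {s}   {prob}")
        add("")
        add("Grouped indexes")
        for name, group in self.indexes.to_dict().items():
            cells = "  ".join(f"{k}={v:.2f}" for k, v in group.items())
            add(f"  {name:<10s} {cells}")
        add("")
        add("Steady state (probability of each state after many transitions)")
        for res in (self.steady_power, self.steady_eigen):
            d = res.distribution.as_dict()
            vals = "  ".join(f"{s}={d[s]:.2f}" for s in STATE_ORDER)
            extra = f", {res.n_steps} steps" if res.n_steps is not None else ""
            add(f"  {res.method:<6s} {vals}   (converged={res.converged}{extra})")
        add("=" * 68)
        return "\n".join(lines)

    def to_report_dict(self) -> dict:
        return {
            "provenance": dict(self.model.provenance, version=_pkg_version),
            "artifact_report": self.artifact_report.to_dict(),
            "rmssd_matrix": _matrix_dict(self.rmssd_matrix.values),
            "transition_matrix": _matrix_dict(self.transition_matrix.values),
            "indexes": self.indexes.to_dict(),
            "steady_state": {
                "power": self.steady_power.to_dict(),
                "eigen": self.steady_eigen.to_dict(),
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_report_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    def export_graph(self, path) -> str:
        return export_graph(self.transition_matrix, path)

    def plot_matrix(self, ax=None):
        """Heatmap of the transition matrix (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        im = ax.imshow(self.transition_matrix.values, cmap="viridis", vmin=0, vmax=1)
        ax.set_xticks(range(4), STATE_ORDER)
        ax.set_yticks(range(4), STATE_ORDER)
        ax.set_xlabel("to state")
        ax.set_ylabel("from state")
        for i in range(4):
            for j in range(4):
                ax.text(
                    j, i, f"{self.transition_matrix.values[i, j]:.2f}",
                    ha="center", va="center", color="white",
                )
        ax.figure.colorbar(im, ax=ax, fraction=0.046)
        return ax


def _matrix_dict(values: np.ndarray) -> dict:
    return {
        a: {b: float(values[i, j]) for j, b in enumerate(STATE_ORDER)}
        for i, a in enumerate(STATE_ORDER)
    }


def run_pipeline(
    rr_path,
    schedule_path,
    out_dir=None,
    rr_format: str = "plain",
    protocol_start_s: float = 0.0,
    correction_level: str = "medium",
    steps: int = 10,
    min_intervals: int = 3,
) -> AffectDynamicsResults:
    """End-to-end analysis: read, correct, window, Markovize, steady states.

    When ``out_dir`` is given, writes ``report.json``, ``rmssd_matrix.csv``,
    ``transition_matrix.csv`` and ``transitions.dot`` there.  Output is
    deterministic for identical inputs (no timestamps).
    """
    model = AffectDynamics.from_files(
        rr_path,
        schedule_path,
        rr_format=rr_format,
        protocol_start_s=protocol_start_s,
        correction_level=correction_level,
        min_intervals=min_intervals,
    )
    results = model.fit(steps=steps)
    if out_dir is not None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        results.to_json(out / "report.json")
        results.rmssd_matrix.to_csv(out / "rmssd_matrix.csv")
        results.transition_matrix.to_csv(out / "transition_matrix.csv")
        results.export_graph(out / "transitions.dot")
    return results
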