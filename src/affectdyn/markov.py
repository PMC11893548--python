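"""Markovization of windowed RMSSD values and steady-state analysis.

The 16 window-wise RMSSD values form a 4x4 matrix over the circumplex states
A (stress), B (engagement), C (boredom), D (relaxation).  Row-relativizing
that matrix — dividing every entry by its row sum, self cell included —
turns raw short-term variability into a row-stochastic transition matrix P:
P_ij is read as the probability of moving from state i to state j in one
step of a discrete-time, discrete-space Markov chain.

Two routes to the stationary distribution are provided: iterated
multiplication of an initial distribution by P (the power method, ten steps
by default) and the left eigenvector of P for eigenvalue 1.  On an
irreducible aperiodic chain they agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import DegenerateRowError, InvalidInputError, NonUniqueSteadyStateError

STATE_ORDER = ("A", "B", "C", "D")

#: Fixed partition of the 16 cells into the four named index groups.
INDEX_GROUPS = {
    "vertical": ("AC", "CA", "BD", "DB"),  # same valence, opposite arousal
    "horizontal": ("AB", "BA", "CD", "DC"),  # same arousal, opposite valence
    "oblique": ("AD", "DA", "BC", "CB"),  # both dimensions change
    "self": ("AA", "BB", "CC", "DD"),  # within-state variability
}


def _cell(pair: str) -> tuple[int, int]:
    return STATE_ORDER.index(pair[0]), STATE_ORDER.index(pair[1])


class _LabeledMatrix:
    """Shared 4x4 container with A-D row/column labels."""

    _value_constraint = "non-negative and finite"

    def __init__(self, values):
        values = np.asarray(values, dtype=float)
        if values.shape != (4, 4):
            raise InvalidInputError(f"expected a 4x4 matrix, got shape {values.shape}")
        if not np.all(np.isfinite(values)) or np.any(values < 0):
            raise InvalidInputError(f"matrix entries must be {self._value_constraint}")
        self.values = values

    def __getitem__(self, pair: str) -> float:
        return float(self.values[_cell(pair)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=STATE_ORDER, columns=STATE_ORDER)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index_label="from")

    @classmethod
    def _read_csv(cls, path) -> np.ndarray:
        df = pd.read_csv(path, index_col=0)
        try:
            df = df.loc[list(STATE_ORDER), list(STATE_ORDER)]
        except KeyError as exc:
            raise InvalidInputError(f"matrix CSV must be labeled A-D: {exc}") from exc
        return df.to_numpy(dtype=float)

    def __repr__(self):
        return f"{type(self).__name__}(\n{self.to_dataframe()!r}\n)"


class RMSSDMatrix(_LabeledMatrix):
    """Raw windowed RMSSD values (ms), rows = from-state, columns = to-state."""

    @classmethod
    def from_csv(cls, path) -> "RMSSDMatrix":
        return cls(cls._read_csv(path))


class TransitionMatrix(_LabeledMatrix):
    """Row-stochastic 4x4 matrix of transition probabilities.

    ``atol`` is the row-sum tolerance: matrices produced by
    :func:`markovize` satisfy 1e-9; matrices re-keyed from figures rounded
    to two decimals are accepted with ``atol=0.02`` (see
    :meth:`from_rounded`).
    """

    _value_constraint = "probabilities in [0, 1]"

    def __init__(self, values, atol: float = 1e-9):
        super().__init__(values)
        if np.any(self.values > 1 + 1e-12):
            raise InvalidInputError("transition probabilities must be <= 1")
        sums = self.values.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > atol):
            raise InvalidInputError(
                f"rows must sum to 1 within {atol}; got {sums.round(6).tolist()}"
            )
        self.atol = atol

    @classmethod
    def from_rounded(cls, values, renormalize: bool = False) -> "TransitionMatrix":
        """Accept a matrix whose rows sum to 1 only within +/-0.02.

        Published matrices printed at two decimals carry rounding error in
        their row sums.  With ``renormalize=False`` (default) the printed
        values are kept verbatim, so downstream computations reproduce what
        the printed figures imply; with ``renormalize=True`` each row is
        rescaled to sum exactly 1.
        """
        m = cls(values, atol=0.02)
        if renormalize:
            return cls(m.values / m.values.sum(axis=1, keepdims=True))
        return m

    @classmethod
    def from_csv(cls, path, atol: float = 0.02, renormalize: bool = False):
        values = cls._read_csv(path)
        m = cls(values, atol=atol)
        if renormalize:
            return cls(m.values / m.values.sum(axis=1, keepdims=True))
        return m

    def row_sums(self) -> np.ndarray:
        return self.values.sum(axis=1)


@dataclass
class StateDistribution:
    """A probability vector over the four states (order A, B, C, D)."""

    probs: np.ndarray
    atol: float = 1e-9

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (4,):
            raise InvalidInputError("state distribution must have 4 entries")
        if np.any(self.probs < -1e-12) or abs(self.probs.sum() - 1.0) > self.atol:
            raise InvalidInputError(
                f"distribution entries must be non-negative and sum to 1 "
                f"within {self.atol}"
            )

    def __getitem__(self, state: str) -> float:
        return float(self.probs[STATE_ORDER.index(state)])

    def as_dict(self) -> dict[str, float]:
        return {s: float(p) for s, p in zip(STATE_ORDER, self.probs)}


@dataclass
class SteadyStateResult:
    distribution: StateDistribution
    method: str  # "power" | "eigen"
    converged: bool
    max_abs_change: float
    n_steps: int | None = None

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "distribution": self.distribution.as_dict(),
            "converged": self.converged,
            "max_abs_change": self.max_abs_change,
        }
        if self.n_steps is not None:
            d["n_steps"] = self.n_steps
        return d


@dataclass
class MarkovIndexes:
    """The 16 transition probabilities grouped by transition geometry."""

    vertical: dict[str, float]
    horizontal: dict[str, float]
    oblique: dict[str, float]
    self_: dict[str, float] = field(default=None)  # type: ignore[assignment]

    def to_dict(self) -> dict:
        return {
            "vertical": self.vertical,
            "horizontal": self.horizontal,
            "oblique": self.oblique,
            "self": self.self_,
        }


def markovize(raw: RMSSDMatrix) -> TransitionMatrix:
    """Row-relativize an RMSSD matrix into a transition matrix.

    ``P_ij = raw_ij / sum_k raw_ik`` — the self cell participates in the
    denominator.  A zero-sum row has no defined probabilities and raises
    :class:`DegenerateRowError`.
    """
    sums = raw.values.sum(axis=1)
    for i, s in enumerate(sums):
        if s <= 0:
            raise DegenerateRowError(STATE_ORDER[i])
    return TransitionMatrix(raw.values / sums[:, None])


def uniform_initial() -> StateDistribution:
    """Equiprobable start: the subject is equally likely in any quadrant."""
    return StateDistribution(np.full(4, 0.25))


def step_distribution(pi: StateDistribution, P: TransitionMatrix) -> StateDistribution:
    """One chain step: the row-vector product pi . P."""
    return StateDistribution(pi.probs @ P.values, atol=max(pi.atol, 4 * P.atol))


def steady_state_power(
    P: TransitionMatrix,
    pi0: StateDistribution | None = None,
    steps: int = 10,
    tol: float = 1e-8,
    renormalize: bool = False,
) -> SteadyStateResult:
    """Iterate ``pi0 . P^n`` for ``steps`` steps.

    ``converged`` reports whether the last step moved any entry by more than
    ``tol`` (sup norm).  When ``P`` carries rounding error in its rows the
    iterate drifts off the simplex; ``renormalize=True`` rescales the final
    vector to sum 1, ``renormalize=False`` (default) returns the raw
    product, which is what iterating a printed rounded matrix implies.
    """
    if steps < 1:
        raise InvalidInputError("steps must be >= 1")
    if pi0 is None:
        pi0 = uniform_initial()
    v = pi0.probs.copy()
    change = np.inf
    for _ in range(steps):
        w = v @ P.values
        change = float(np.abs(w - v).max())
        v = w
    if renormalize:
        v = v / v.sum()
    dist = StateDistribution(v, atol=max(1e-9, 20 * P.atol))
    return SteadyStateResult(
        distribution=dist,
        method="power",
        converged=change <= tol,
        max_abs_change=change,
        n_steps=steps,
    )


def _check_ergodic(P: TransitionMatrix) -> None:
    g = nx.DiGraph()
    g.add_nodes_from(range(4))
    for i in range(4):
        for j in range(4):
            if P.values[i, j] > 0:
                g.add_edge(i, j)
    if not nx.is_strongly_connected(g):
        raise NonUniqueSteadyStateError("chain is reducible: steady state not unique")
    if not nx.is_aperiodic(g):
        raise NonUniqueSteadyStateError("chain is periodic: iterates do not converge")


def steady_state_eigen(P: TransitionMatrix) -> SteadyStateResult:
    """Stationary distribution as the left eigenvector of P for eigenvalue 1.

    Requires an irreducible, aperiodic chain (checked on the sparsity
    pattern); otherwise the stationary distribution is not unique and
    :class:`NonUniqueSteadyStateError` is raised.
    """
    _check_ergodic(P)
    eigvals, eigvecs = np.linalg.eig(P.values.T)
    idx = int(np.argmin(np.abs(eigvals - 1.0)))
    vec = np.real(eigvecs[:, idx])
    vec = vec / vec.sum()
    vec = np.clip(vec, 0.0, None)
    vec = vec / vec.sum()
    dist = StateDistribution(vec)
    residual = float(np.abs(vec @ P.values - vec).max())
    return SteadyStateResult(
        distribution=dist,
        method="eigen",
        converged=residual <= max(1e-8, 20 * P.atol),
        max_abs_change=residual,
    )


def grouped_indexes(P: TransitionMatrix) -> MarkovIndexes:
    """Split the 16 probabilities into vertical/horizontal/oblique/self groups."""
    groups = {
        name: {pair: P[pair] for pair in pairs} for name, pairs in INDEX_GROUPS.items()
    }
    return MarkovIndexes(
        vertical=groups["vertical"],
        horizontal=groups["horizontal"],
        oblique=groups["oblique"],
        self_=groups["self"],
    )
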