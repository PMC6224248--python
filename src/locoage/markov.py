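"""Markov-chain description of per-minute activity tracks.

Per-minute activity counts are discretized into a small alphabet of
activity states (8 by default, log-spaced bin edges), transitions between
consecutive minutes are counted, and the column-stochastic transition
matrix ``T`` is estimated together with its continuous-time generator
``W = T - I``.  The flattened, floor-imputed, log-scaled transition matrix
is the 64-dimensional descriptor used by the biological-age and hazard
models downstream.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DEFAULT_N_STATES",
    "DESCRIPTOR_FLOOR",
    "DiscretizationScheme",
    "StateSequence",
    "TransitionModel",
    "discretize",
    "count_transitions",
    "transition_matrix",
    "estimate_transition_model",
    "log_descriptor",
    "descriptor_names",
]

DEFAULT_N_STATES = 8

#: Elements of T below this value are floored before log-scaling; for a
#: 7-day track this corresponds to fewer than ~10 observed transitions.
DESCRIPTOR_FLOOR = 1e-3


def _default_edges() -> np.ndarray:
    # b_k = e^k - 1 for k = 1..7: log-spaced count thresholds
    return np.exp(np.arange(1, DEFAULT_N_STATES)) - 1.0


@dataclass(frozen=True)
class DiscretizationScheme:
    """Bin edges mapping activity counts to discrete activity states.

    A value ``a`` is assigned state 0 when ``a < edges[0]``, state k
    (1 <= k < K-1) when ``edges[k-1] <= a < edges[k]`` and the top state
    when ``a >= edges[-1]``.
    """

    edges: np.ndarray = field(default_factory=_default_edges)
    #: activity-count edges must be positive; harmonized (log-PSD scale)
    #: edges may be negative and set this to False
    require_positive: bool = True

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=float)
        if edges.ndim != 1 or edges.size < 1:
            raise ValueError("edges must be a non-empty 1-d array")
        if not np.all(np.diff(edges) > 0):
            raise ValueError("edges must be strictly increasing")
        if self.require_positive and not np.all(edges > 0):
            raise ValueError("count bin edges must be positive")
        object.__setattr__(self, "edges", edges)

    @property
    def n_states(self) -> int:
        return self.edges.size + 1


@dataclass
class StateSequence:
    """Per-minute activity states plus the contiguous valid segments.

    Transitions are only counted within a segment; a segment boundary
    (e.g. an excluded non-wear day) never contributes a pair.
    """

    states: np.ndarray
    n_states: int = DEFAULT_N_STATES
    #: half-open (start, stop) index pairs; default: one segment = whole track
    segments: list[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int64)
        if self.states.ndim != 1:
            raise ValueError("states must be 1-d")
        if self.states.size and (
            self.states.min() < 0 or self.states.max() >= self.n_states
        ):
            raise ValueError("states outside the alphabet 0..%d" % (self.n_states - 1))
        if self.segments is None:
            self.segments = [(0, self.states.size)]
        else:
            prev_stop = 0
            for start, stop in self.segments:
                if not (0 <= start <= stop <= self.states.size):
                    raise ValueError("segment out of bounds")
                if start < prev_stop:
                    raise ValueError("segments must be ordered and non-overlapping")
                prev_stop = stop


@dataclass
class TransitionModel:
    """Estimated (or analytic) Markov chain over the activity alphabet.

    ``T`` is column-stochastic: ``T[i, j]`` is the probability of moving
    from state ``j`` to state ``i`` in one minute, estimated as
    ``N(j->i) / N(j)``.  ``W = T - I`` is the generator; its nonzero
    eigenvalues are negative inverse relaxation times.
    """

    T: np.ndarray
    counts: np.ndarray | None = None
    occupancy: np.ndarray | None = None

    def __post_init__(self) -> None:
        T = np.asarray(self.T, dtype=float)
        if T.ndim != 2 or T.shape[0] != T.shape[1]:
            raise ValueError("T must be square")
        if np.any(T < -1e-12) or np.any(T > 1 + 1e-12):
            raise ValueError("T entries must lie in [0, 1]")
        colsums = T.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-8):
            raise ValueError("columns of T must sum to 1")
        self.T = T

    @property
    def n_states(self) -> int:
        return self.T.shape[0]

    @property
    def W(self) -> np.ndarray:
        return self.T - np.eye(self.n_states)

    @property
    def visited(self) -> np.ndarray:
        """States actually observed (occupied or entered); all if analytic."""
        if self.occupancy is None:
            return np.ones(self.n_states, dtype=bool)
        entered = self.counts.sum(axis=1) > 0 if self.counts is not None else False
        return (self.occupancy > 0) | entered

    @classmethod
    def from_matrix(cls, T: np.ndarray) -> "TransitionModel":
        return cls(T=np.asarray(T, dtype=float))


def discretize(
    counts: np.ndarray, scheme: DiscretizationScheme | None = None
) -> StateSequence:
    """Map per-minute values to activity states via the scheme's bin edges."""
    scheme = scheme or DiscretizationScheme()
    a = np.asarray(counts, dtype=float)
    if scheme.require_positive and a.size and a.min() < 0:
        row = int(np.argmin(a))
        raise ValueError(f"negative activity count at minute {row}: {a[row]}")
    states = np.searchsorted(scheme.edges, a, side="right")
    return StateSequence(states=states, n_states=scheme.n_states)


def count_transitions(seq: StateSequence) -> tuple[np.ndarray, np.ndarray]:
    """Count within-segment transition pairs.

    Returns ``(C, N)`` where ``C[i, j]`` is the number of times state ``j``
    was immediately followed by state ``i`` and ``N[j]`` the number of
    minutes in state ``j`` that have a successor within the same segment
    (so visited columns of ``C / N`` sum exactly to one).
    """
    K = seq.n_states
    if seq.states.size == 0:
        raise ValueError("empty state sequence")
    C = np.zeros((K, K), dtype=np.int64)
    for start, stop in seq.segments:
        s = seq.states[start:stop]
        if s.size < 2:
            continue
        np.add.at(C, (s[1:], s[:-1]), 1)
    if C.sum() == 0:
        raise ValueError("no within-segment transition pairs")
    N = C.sum(axis=0)
    return C, N


def transition_matrix(C: np.ndarray, N: np.ndarray) -> TransitionModel:
    """``T[i, j] = C[i, j] / N[j]``; unvisited columns become identity columns."""
    C = np.asarray(C)
    N = np.asarray(N)
    K = C.shape[0]
    if C.shape != (K, K) or N.shape != (K,):
        raise ValueError("inconsistent shapes for C and N")
    if not np.array_equal(C.sum(axis=0), N):
        raise ValueError("N must equal the column sums of C")
    T = np.eye(K)
    vis = N > 0
    T[:, vis] = C[:, vis] / N[vis]
    return TransitionModel(T=T, counts=C, occupancy=N)


def estimate_transition_model(
    counts_or_seq, scheme: DiscretizationScheme | None = None
) -> TransitionModel:
    """Convenience: counts (or a StateSequence) -> TransitionModel."""
    seq = (
        counts_or_seq
        if isinstance(counts_or_seq, StateSequence)
        else discretize(counts_or_seq, scheme)
    )
    C, N = count_transitions(seq)
    return transition_matrix(C, N)


def log_descriptor(
    tm: TransitionModel, floor: float = DESCRIPTOR_FLOOR
) -> np.ndarray:
    """Flattened, floored, log-scaled transition matrix.

    Near-zero elements (< ``floor``) are imputed by ``floor`` before
    taking the natural log.  Flattening is column-major (all destination
    states of source state 0 first), fixed so that training and scoring
    always agree.
    """
    return np.log(np.maximum(tm.T, floor)).flatten(order="F")


def descriptor_names(n_states: int = DEFAULT_N_STATES) -> list[str]:
    """Column names for the flattened descriptor, matching its fixed order."""
    return [f"t_{i}_{j}" for j in range(n_states) for i in range(n_states)]
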