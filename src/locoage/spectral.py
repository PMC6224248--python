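"""Spectral characterization of activity-state Markov chains.

The generator ``W = T - I`` of a reversible chain has a real spectrum;
its nonzero eigenvalues are negative inverse relaxation times
("eigenfrequencies", per minute).  For a reversible chain the stationary
autocovariance of any state observable is a sum of decaying exponentials,
so the power spectral density is a sum of Lorentzians

    PSD(omega) = sum_m c_m * 2*lambda_m / (lambda_m^2 + omega^2),

with ``sum_m c_m`` equal to the stationary variance of the observable.
The corner (crossover) frequency of the PSD is set by the slowest
relaxation rate, which shifts upward with age in the data this package
models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.signal
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .markov import TransitionModel

__all__ = [
    "SpectralSummary",
    "ReducibleChainError",
    "stationary_distribution",
    "detailed_balance_score",
    "eigenfrequencies",
    "reconstruct_psd",
    "empirical_psd",
    "summarize",
]

#: chains with a detailed-balance asymmetry below this are treated as reversible
DB_TOLERANCE = 0.1

#: eigenvalues of W with magnitude below this are trivial (stationary) modes
ZERO_MODE_TOL = 1e-10


class ReducibleChainError(ValueError):
    """The chain has more than one closed communicating class."""


@dataclass
class SpectralSummary:
    pi: np.ndarray
    eigenrates: np.ndarray
    db_score: float
    psd: tuple[np.ndarray, np.ndarray] | None = None


def _visited_submatrix(tm: TransitionModel) -> tuple[np.ndarray, np.ndarray]:
    vis = tm.visited
    idx = np.flatnonzero(vis)
    sub = tm.T[np.ix_(idx, idx)]
    # transitions never leave the visited set, so columns still sum to 1
    if not np.allclose(sub.sum(axis=0), 1.0, atol=1e-8):
        raise ValueError("transitions leak out of the visited state set")
    return sub, idx


def stationary_distribution(tm: TransitionModel) -> np.ndarray:
    """Stationary distribution pi with ``T pi = pi`` on the visited states.

    Unvisited states get probability 0.  Raises
    :class:`ReducibleChainError` if the visited chain splits into several
    closed communicating classes (e.g. the identity chain, where every
    state is absorbing).
    """
    sub, idx = _visited_submatrix(tm)
    n_comp, labels = connected_components(
        csr_matrix(sub > 0), directed=True, connection="strong"
    )
    if n_comp > 1:
        classes = [list(idx[labels == c]) for c in range(n_comp)]
        raise ReducibleChainError(
            f"chain is reducible; communicating classes (original labels): {classes}"
        )
    evals, evecs = np.linalg.eig(sub)
    k = int(np.argmin(np.abs(evals - 1.0)))
    v = np.real(evecs[:, k])
    v = np.abs(v)
    v = v / v.sum()
    pi = np.zeros(tm.n_states)
    pi[idx] = v
    return pi


def detailed_balance_score(
    tm: TransitionModel, pi: np.ndarray | None = None
) -> float:
    """Relative asymmetry of the stationary probability flux.

    With flux ``F[i, j] = T[i, j] * pi[j]``, returns
    ``||F - F^T||_F / ||F||_F``; 0 means exact reversibility.
    """
    if pi is None:
        pi = stationary_distribution(tm)
    F = tm.T * pi[np.newaxis, :]
    denom = np.linalg.norm(F)
    if denom == 0:
        return 0.0
    return float(np.linalg.norm(F - F.T) / denom)


def eigenfrequencies(
    tm: TransitionModel,
    zero_tol: float = ZERO_MODE_TOL,
    imag_tol: float = 1e-8,
) -> np.ndarray:
    """Relaxation rates: negated nonzero eigenvalues of W, sorted ascending.

    One zero mode per closed class (the stationary mode) is excluded.  For
    a reversible chain all rates are real and lie in [0, 2]; a warning is
    raised if eigenvalues carry imaginary parts beyond tolerance while the
    chain scores as reversible.
    """
    evals = np.linalg.eigvals(tm.W)
    nonzero = evals[np.abs(evals) > zero_tol]
    if nonzero.size and np.max(np.abs(nonzero.imag)) > imag_tol:
        try:
            reversible = detailed_balance_score(tm) < DB_TOLERANCE
        except ReducibleChainError:
            reversible = False
        if reversible:
            warnings.warn(
                "complex generator eigenvalues on a chain scoring as reversible",
                RuntimeWarning,
            )
    rates = np.sort(-nonzero.real)
    return rates


def reconstruct_psd(
    tm: TransitionModel,
    observable: np.ndarray | None = None,
    freqs: np.ndarray | None = None,
    db_tol: float = DB_TOLERANCE,
    kind: str = "angular",
) -> tuple[np.ndarray, np.ndarray]:
    """Lorentzian-sum PSD of a state observable under the fitted chain.

    The pi-symmetrized generator is eigendecomposed; the squared
    pi-weighted projections of the observable onto the non-stationary
    eigenmodes give the Lorentzian weights ``c_m`` (their sum is the
    stationary variance of the observable).

    Parameters
    ----------
    observable : value per state; defaults to the state index, a
        log-activity proxy (states are log-spaced in counts).
    freqs : evaluation grid.  ``kind="angular"``: two-sided density on an
        angular-frequency grid (rad/min), integrating to 2*pi*variance.
        ``kind="cyclic"``: one-sided density on a cycles/min grid,
        directly comparable to a Welch estimate at 1/min sampling.
    """
    if kind not in ("angular", "cyclic"):
        raise ValueError("kind must be 'angular' or 'cyclic'")
    pi = stationary_distribution(tm)
    score = detailed_balance_score(tm, pi)
    if score > db_tol:
        raise ValueError(
            f"detailed-balance score {score:.3g} exceeds {db_tol}; "
            "Lorentzian reconstruction assumes a real (reversible) spectrum"
        )
    if observable is None:
        observable = np.arange(tm.n_states, dtype=float)
    f = np.asarray(observable, dtype=float)
    if f.shape != (tm.n_states,):
        raise ValueError("observable must give one value per state")
    idx = np.flatnonzero(pi > 0)
    pi_v, f_v = pi[idx], f[idx]
    W_v = tm.W[np.ix_(idx, idx)]
    sq = np.sqrt(pi_v)
    S = W_v * (sq[np.newaxis, :] / sq[:, np.newaxis])
    S = 0.5 * (S + S.T)  # symmetric up to roundoff once reversibility holds
    evals, evecs = np.linalg.eigh(S)
    lam = -evals
    g = f_v * sq
    proj = evecs.T @ g
    keep = lam > ZERO_MODE_TOL
    lam, c = lam[keep], proj[keep] ** 2
    if freqs is None:
        hi = 2.0 * np.pi * 0.5  # Nyquist of 1/min sampling, in rad/min
        freqs = np.linspace(0.0, hi, 513)
    freqs = np.asarray(freqs, dtype=float)
    omega = 2.0 * np.pi * freqs if kind == "cyclic" else freqs
    psd = np.sum(
        c[:, None] * 2.0 * lam[:, None] / (lam[:, None] ** 2 + omega[None, :] ** 2),
        axis=0,
    )
    if kind == "cyclic":
        psd = 2.0 * psd
    return freqs, psd


def empirical_psd(
    x: np.ndarray,
    fs: float = 1.0,
    nperseg: int = 1024,
    window: str = "hann",
) -> tuple[np.ndarray, np.ndarray]:
    """Welch-averaged one-sided periodogram of a per-minute series.

    Defaults: 1024-sample segments, Hann taper, 50% overlap, at 1/min
    sampling.  Directly comparable to ``reconstruct_psd(..., kind="cyclic")``.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2 * nperseg:
        raise ValueError(
            f"series too short for Welch estimate: {x.size} < 2*{nperseg}"
        )
    return scipy.signal.welch(
        x, fs=fs, window=window, nperseg=nperseg, noverlap=nperseg // 2
    )


def summarize(
    tm: TransitionModel,
    observable: np.ndarray | None = None,
    freqs: np.ndarray | None = None,
    with_psd: bool = True,
) -> SpectralSummary:
    pi = stationary_distribution(tm)
    db = detailed_balance_score(tm, pi)
    rates = eigenfrequencies(tm)
    psd = None
    if with_psd and db < DB_TOLERANCE:
        psd = reconstruct_psd(tm, observable=observable, freqs=freqs)
    return SpectralSummary(pi=pi, eigenrates=rates, db_score=db, psd=psd)
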