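"""State-based synchrony: symbolic entropy and multidimensional RQA.

Both metrics treat the joint configuration of all variables at each time
step as one system state.  Symbolic entropy discretizes every channel into
terciles and measures the Shannon entropy of the joint symbol stream;
multidimensional recurrence quantification analysis (mdRQA) thresholds the
Euclidean distances between joint states and summarizes the diagonal-line
structure of the resulting recurrence matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .core import DegenerateSignalError, ParameterError, ValidationError, as_array

__all__ = [
    "SymbolSequence",
    "RecurrenceMatrix",
    "RQAMetrics",
    "discretize_terciles",
    "symbolic_entropy",
    "recurrence_matrix",
    "rqa_metrics",
    "tune_radius",
]


@dataclass
class SymbolSequence:
    """Joint low/medium/high symbols, one per time step.

    ``symbols[t]`` is the base-3 encoding (variable 0 most significant) of
    the per-variable tercile levels at time t; the alphabet has 3**n_variables
    possible states.
    """

    symbols: np.ndarray
    alphabet_size: int
    levels: np.ndarray  # (n_variables, n_timesteps) tercile levels in {0,1,2}


def _tercile_levels(x: np.ndarray) -> np.ndarray:
    """Map one channel to levels {0,1,2} at its nearest-rank tercile boundaries.

    Values exactly on a boundary go to the lower level, so the split is
    deterministic and invariant under strictly monotone transforms.
    """
    n = x.size
    srt = np.sort(x)
    q1 = srt[int(np.ceil(n / 3.0)) - 1]
    q2 = srt[int(np.ceil(2.0 * n / 3.0)) - 1]
    return np.where(x <= q1, 0, np.where(x <= q2, 1, 2))


def discretize_terciles(series) -> SymbolSequence:
    """Per-variable tercile discretization and joint base-3 symbol encoding."""
    values = as_array(series)
    n_var, n_t = values.shape
    if n_t < 3:
        raise ValidationError("tercile discretization needs >= 3 time steps")
    if np.any(np.ptp(values, axis=1) == 0):
        bad = int(np.flatnonzero(np.ptp(values, axis=1) == 0)[0])
        raise DegenerateSignalError(f"variable {bad} is constant; terciles are degenerate")
    levels = np.vstack([_tercile_levels(row) for row in values])
    weights = 3 ** np.arange(n_var - 1, -1, -1)
    symbols = weights @ levels
    return SymbolSequence(symbols=symbols, alphabet_size=3**n_var, levels=levels)


def symbolic_entropy(series, base: float | None = None) -> float:
    """Shannon entropy of the empirical joint-symbol distribution.

    Natural-log units (nats) by default, so a perfectly synchronized system
    scores ln 3 (the three tercile states cycle together) and n independent
    uniform channels approach n * ln 3.  Pass ``base`` for other units.
    """
    seq = discretize_terciles(series)
    _, counts = np.unique(seq.symbols, return_counts=True)
    p = counts / counts.sum()
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


@dataclass
class RecurrenceMatrix:
    """Binary recurrence structure of the joint state trajectory."""

    cells: np.ndarray  # (n_points, n_points) bool, symmetric, diagonal True
    radius: float
    normalized: bool
    embedding: tuple[int, int]  # (dimension m, delay tau)

    @property
    def n_points(self) -> int:
        return self.cells.shape[0]


def _embed(values: np.ndarray, m: int, tau: int) -> np.ndarray:
    """Time-delay embedding: state t concatenates all variables at lags 0..(m-1)*tau.

    Returns an (n_points, n_variables * m) array of state vectors.
    """
    n_var, n_t = values.shape
    n_points = n_t - (m - 1) * tau
    parts = [values[:, k * tau : k * tau + n_points] for k in range(m)]
    return np.vstack(parts).T


def recurrence_matrix(
    series,
    radius: float,
    normalize: bool = True,
    embedding: tuple[int, int] = (1, 1),
) -> RecurrenceMatrix:
    """Threshold the Euclidean distances between joint states.

    With ``normalize`` each variable is standardized to mean 0, variance 1
    before distances are computed, making the radius scale-free.  Embedding
    (m, tau) with m > 1 compares lag-stacked state vectors; the default
    (1, 1) compares raw joint states, since embedding is optional for mdRQA.
    """
    values = as_array(series)
    if radius <= 0:
        raise ParameterError(f"radius must be positive, got {radius}")
    m, tau = embedding
    if m < 1 or tau < 1:
        raise ParameterError(f"embedding needs m >= 1 and tau >= 1, got {embedding}")
    if m > 1 and values.shape[1] <= (m - 1) * tau:
        raise ParameterError(
            f"series of length {values.shape[1]} too short for embedding {embedding}"
        )
    if normalize:
        sd = values.std(axis=1, keepdims=True)
        if np.any(sd == 0):
            raise DegenerateSignalError("constant variable cannot be standardized")
        values = (values - values.mean(axis=1, keepdims=True)) / sd
    states = _embed(values, m, tau)
    cells = squareform(pdist(states) <= radius).astype(bool)
    np.fill_diagonal(cells, True)
    return RecurrenceMatrix(cells=cells, radius=float(radius), normalized=normalize,
                            embedding=(m, tau))


@dataclass
class RQAMetrics:
    """Diagonal-line summaries of a recurrence matrix, main diagonal excluded.

    rec_pct: % of off-diagonal cells that are recurrent.
    det_pct: % of off-diagonal recurrent cells lying on diagonal runs of
        length >= min_line.
    adl: mean length (steps) of those qualifying runs.
    maxl: longest off-main-diagonal run of any length.
    """

    rec_pct: float
    det_pct: float
    adl: float
    maxl: int


def _run_lengths(diag: np.ndarray) -> np.ndarray:
    padded = np.concatenate(([0], diag.astype(np.int8), [0]))
    d = np.diff(padded)
    return np.flatnonzero(d == -1) - np.flatnonzero(d == 1)


def rqa_metrics(rm: RecurrenceMatrix | np.ndarray, min_line: int = 2) -> RQAMetrics:
    """%REC, %DET, average and maximum diagonal line length.

    Runs are counted on both triangles; the main diagonal (trivially all
    recurrent) is excluded everywhere.  A matrix with no off-diagonal
    recurrence yields det_pct = adl = maxl = 0.
    """
    if min_line < 2:
        raise ParameterError(f"min_line must be >= 2, got {min_line}")
    cells = rm.cells if isinstance(rm, RecurrenceMatrix) else np.asarray(rm, dtype=bool)
    if cells.ndim != 2 or cells.shape[0] != cells.shape[1]:
        raise ValidationError("recurrence matrix must be square")
    n = cells.shape[0]
    off_recurrent = int(cells.sum() - np.trace(cells))
    rec_pct = 100.0 * off_recurrent / (n * n - n)
    runs = [
        lengths
        for k in range(1, n)
        for lengths in (_run_lengths(cells.diagonal(k)), _run_lengths(cells.diagonal(-k)))
        if lengths.size
    ]
    all_runs = np.concatenate(runs) if runs else np.empty(0, dtype=int)
    qualifying = all_runs[all_runs >= min_line]
    det_pct = 100.0 * qualifying.sum() / off_recurrent if off_recurrent else 0.0
    adl = float(qualifying.mean()) if qualifying.size else 0.0
    maxl = int(all_runs.max()) if all_runs.size else 0
    return RQAMetrics(rec_pct=rec_pct, det_pct=float(det_pct), adl=adl, maxl=maxl)


def tune_radius(
    series,
    target_rec: float = 3.0,
    tolerance: float = 2.0,
    normalize: bool = True,
    embedding: tuple[int, int] = (1, 1),
    max_iter: int = 60,
) -> float:
    """Bisect the radius until %REC lands inside [target - tol, target + tol].

    Practitioners typically aim for 1-5% recurrence; the default band is
    exactly that.  %REC is non-decreasing in radius, so bisection converges.
    The helper only proposes a radius; it is never applied silently.
    """
    values = as_array(series)
    if normalize:
        sd = values.std(axis=1, keepdims=True)
        if np.any(sd == 0):
            raise DegenerateSignalError("constant variable cannot be standardized")
        values = (values - values.mean(axis=1, keepdims=True)) / sd
    m, tau = embedding
    states = _embed(values, m, tau)
    distances = pdist(states)
    lo, hi = float(np.min(distances[distances > 0], initial=1e-12)), float(distances.max())
    n = states.shape[0]
    total = n * n - n

    def rec_at(r: float) -> float:
        return 100.0 * 2.0 * int((distances <= r).sum()) / total

    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        rec = rec_at(mid)
        if abs(rec - target_rec) <= tolerance:
            return mid
        if rec < target_rec:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
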