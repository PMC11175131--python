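"""Dynamic time warping between a reference (class) and a test sequence.

The stability score of a gait cycle is the minimal cumulative squared-Euclidean
alignment cost between the participant's reference cycle ``C`` (length ``I``)
and the test cycle ``T`` (length ``J``):

    DTW(C, T) = min over warp paths W of  sum_q (C[i_q] - T[j_q])**2

where a warp path starts at ``(0, 0)``, ends at ``(I-1, J-1)``, moves by steps
of ``(1, 0)``, ``(0, 1)`` or ``(1, 1)``, and therefore has length
``max(I, J) <= Q <= I + J - 1``.  No global window constraint and no
path-length normalisation are applied; raw costs are compared across trials.

The dynamic program is the contribution this module exists for, so it is
written from scratch (numba-compiled for speed).  ``dtw_bruteforce_oracle``
enumerates every valid warp path on tiny inputs and is used by the test suite
as an independent check of the recurrence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .errors import DataError, SizeError

__all__ = [
    "DtwResult",
    "local_distance",
    "build_distance_matrix",
    "dtw_align",
    "dtw_distance",
    "dtw_bruteforce_oracle",
    "enumerate_warp_paths",
]


@dataclass(frozen=True)
class DtwResult:
    """Minimal cumulative warping cost and one minimising warp path.

    ``path`` is a list of 0-based ``(i, j)`` index pairs from ``(0, 0)`` to
    ``(I-1, J-1)``.
    """

    distance: float
    path: tuple[tuple[int, int], ...]


def local_distance(c: float, t: float) -> float:
    """Squared-Euclidean local distance ``(c - t)**2`` between two samples."""
    if not (np.isfinite(c) and np.isfinite(t)):
        raise DataError(f"non-finite input to local_distance: ({c}, {t})")
    d = float(c) - float(t)
    return d * d


def _as_series(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=np.float64)
    if arr.ndim != 1 or arr.size == 0:
        raise DataError(f"{name} must be a non-empty 1-d sequence")
    if not np.all(np.isfinite(arr)):
        raise DataError(f"{name} contains non-finite values")
    return arr


def build_distance_matrix(C, T) -> np.ndarray:
    """Local-distance matrix ``d[i, j] = (C[i] - T[j])**2`` of shape (I, J)."""
    c = _as_series(C, "C")
    t = _as_series(T, "T")
    diff = c[:, None] - t[None, :]
    return diff * diff


@njit(cache=True)
def _cumulative_cost(c, t):  # pragma: no cover - exercised via wrappers
    I = c.shape[0]
    J = t.shape[0]
    g = np.empty((I, J), dtype=np.float64)
    d0 = c[0] - t[0]
    g[0, 0] = d0 * d0
    for j in range(1, J):
        d = c[0] - t[j]
        g[0, j] = g[0, j - 1] + d * d
    for i in range(1, I):
        d = c[i] - t[0]
        g[i, 0] = g[i - 1, 0] + d * d
        for j in range(1, J):
            d = c[i] - t[j]
            best = g[i - 1, j - 1]
            if g[i - 1, j] < best:
                best = g[i - 1, j]
            if g[i, j - 1] < best:
                best = g[i, j - 1]
            g[i, j] = best + d * d
    return g


def dtw_distance(C, T) -> float:
    """Minimal cumulative DTW cost without materialising the warp path."""
    c = _as_series(C, "C")
    t = _as_series(T, "T")
    return float(_cumulative_cost(c, t)[-1, -1])


def dtw_align(C, T) -> DtwResult:
    """Align two sequences, returning the minimal cost and one optimal path.

    Backtracking breaks ties by preferring the diagonal predecessor, then the
    vertical one ``(i-1, j)``, then the horizontal one ``(i, j-1)``, so the
    returned path is deterministic.
    """
    c = _as_series(C, "C")
    t = _as_series(T, "T")
    g = _cumulative_cost(c, t)
    i, j = g.shape[0] - 1, g.shape[1] - 1
    rev = [(i, j)]
    while i > 0 or j > 0:
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            diag, vert, horiz = g[i - 1, j - 1], g[i - 1, j], g[i, j - 1]
            if diag <= vert and diag <= horiz:
                i, j = i - 1, j - 1
            elif vert <= horiz:
                i -= 1
            else:
                j -= 1
        rev.append((i, j))
    return DtwResult(distance=float(g[-1, -1]), path=tuple(reversed(rev)))


_ORACLE_CAP = 8


def enumerate_warp_paths(I: int, J: int) -> list[tuple[tuple[int, int], ...]]:
    """Every warp path from (0, 0) to (I-1, J-1) under the step set
    {(1,0), (0,1), (1,1)}.  Exponential; capped at I, J <= 8."""
    if I > _ORACLE_CAP or J > _ORACLE_CAP:
        raise SizeError(f"path enumeration capped at {_ORACLE_CAP}")
    paths: list[tuple[tuple[int, int], ...]] = []

    def walk(i: int, j: int, acc: list[tuple[int, int]]) -> None:
        if i == I - 1 and j == J - 1:
            paths.append(tuple(acc))
            return
        for di, dj in ((1, 1), (1, 0), (0, 1)):
            ni, nj = i + di, j + dj
            if ni < I and nj < J:
                acc.append((ni, nj))
                walk(ni, nj, acc)
                acc.pop()

    walk(0, 0, [(0, 0)])
    return paths


def dtw_bruteforce_oracle(C, T) -> DtwResult:
    """Definition-level DTW: minimum cost over all enumerated warp paths.

    Only feasible for sequences of length <= 8; serves as the independent
    oracle for :func:`dtw_align`.
    """
    c = _as_series(C, "C")
    t = _as_series(T, "T")
    if c.size > _ORACLE_CAP or t.size > _ORACLE_CAP:
        raise SizeError(f"brute-force oracle capped at length {_ORACLE_CAP}")
    d = build_distance_matrix(c, t)
    best_cost = np.inf
    best_path: tuple[tuple[int, int], ...] | None = None
    for path in enumerate_warp_paths(c.size, t.size):
        cost = sum(d[i, j] for i, j in path)
        if cost < best_cost:
            best_cost = cost
            best_path = path
    assert best_path is not None
    return DtwResult(distance=float(best_cost), path=best_path)
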