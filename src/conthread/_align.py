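"""Affine-gap global alignment core (Gotoh three-state recursion).

Shared by feature-based threading alignment, spectral contact-map-overlap
alignment and sequence-identity computation.  The dynamic programme is
compiled with numba; similarity matrices are computed by the callers with
vectorised numpy so the hot loop only reads a dense ``S[i, j]`` matrix.

States: M (i aligned to j), X (query residue against a gap, "up"),
Y (template residue against a gap, "left").  Gap runs cost
``gap_open`` for the first gapped position and ``gap_ext`` for each
further one.  Traceback ties break deterministically M > X > Y.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_NEG = -1e30


@njit(cache=True)
def _gotoh_fill(S, gap_open, gap_ext):  # pragma: no cover - exercised via wrappers
    n, m = S.shape
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)
    Y = np.full((n + 1, m + 1), _NEG)
    PM = np.zeros((n + 1, m + 1), np.int8)
    PX = np.zeros((n + 1, m + 1), np.int8)
    PY = np.zeros((n + 1, m + 1), np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + gap_ext * (i - 1)
        PX[i, 0] = 0 if i == 1 else 1
    for j in range(1, m + 1):
        Y[0, j] = gap_open + gap_ext * (j - 1)
        PY[0, j] = 0 if j == 1 else 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            # aligned state; ties prefer M, then X, then Y
            best = M[i - 1, j - 1]
            p = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                p = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                p = 2
            M[i, j] = best + S[i - 1, j - 1]
            PM[i, j] = p
            # gap in template (consume query i); switching gap direction
            # re-opens the gap
            best = M[i - 1, j] + gap_open
            p = 0
            if X[i - 1, j] + gap_ext > best:
                best = X[i - 1, j] + gap_ext
                p = 1
            if Y[i - 1, j] + gap_open > best:
                best = Y[i - 1, j] + gap_open
                p = 2
            X[i, j] = best
            PX[i, j] = p
            # gap in query (consume template j)
            best = M[i, j - 1] + gap_open
            p = 0
            if X[i, j - 1] + gap_open > best:
                best = X[i, j - 1] + gap_open
                p = 1
            if Y[i, j - 1] + gap_ext > best:
                best = Y[i, j - 1] + gap_ext
                p = 2
            Y[i, j] = best
            PY[i, j] = p
    return M, X, Y, PM, PX, PY


def global_align_score(S: np.ndarray, gap_open: float, gap_ext: float) -> float:
    """Optimal global alignment score for similarity matrix ``S``."""
    S = np.ascontiguousarray(S, dtype=np.float64)
    if S.shape[0] == 0 or S.shape[1] == 0:
        raise ValueError("cannot align empty profiles")
    M, X, Y, *_ = _gotoh_fill(S, float(gap_open), float(gap_ext))
    return float(max(M[-1, -1], X[-1, -1], Y[-1, -1]))


def global_align(
    S: np.ndarray, gap_open: float, gap_ext: float
) -> tuple[float, list[tuple[int, int]]]:
    """Optimal global alignment with traceback.

    Returns ``(score, pairs)`` where pairs are 0-based ``(i, j)`` aligned
    positions, strictly increasing in both coordinates.
    """
    S = np.ascontiguousarray(S, dtype=np.float64)
    n, m = S.shape
    if n == 0 or m == 0:
        raise ValueError("cannot align empty profiles")
    M, X, Y, PM, PX, PY = _gotoh_fill(S, float(gap_open), float(gap_ext))
    ends = (M[n, m], X[n, m], Y[n, m])
    state = int(np.argmax(ends))  # argmax keeps the first max: M > X > Y
    score = float(ends[state])
    pairs: list[tuple[int, int]] = []
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:
            pairs.append((i - 1, j - 1))
            state = int(PM[i, j])
            i -= 1
            j -= 1
        elif state == 1:
            state = int(PX[i, j])
            i -= 1
        else:
            state = int(PY[i, j])
            j -= 1
    pairs.reverse()
    return score, pairs
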