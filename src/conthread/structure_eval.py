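"""Model-vs-native structure comparison: Kabsch superposition RMSD and
TM-score with correct-fold calling.

TM-score is length-normalised so a random pair of structures scores
~0.17 regardless of size, and a score above 0.5 indicates the same
overall fold.  For a model indexed on the native's residue numbering,

    TM = max over superpositions of (1/L) * sum_i 1 / (1 + (d_i/d0)^2),
    d0 = max(1.24 * (L - 15)^(1/3) - 1.8, 0.5),

where L is the native length, the sum runs over residues the model
actually places, and d_i is the model-native C-alpha distance after
superposition.  Missing residues contribute 0, penalising incomplete
models.  The maximisation uses the standard seed-fragment heuristic:
superpose on sliding windows of several lengths, then iteratively
re-superpose on the residues currently within a distance cutoff until the
inclusion set is stable, keeping the best score seen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contact_io import ProteinStructure

__all__ = ["SuperpositionResult", "kabsch", "tm_score", "tm_d0", "correct_fold"]


@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray  # 3x3 proper rotation
    translation: np.ndarray  # 3-vector: model -> rotation @ x + translation
    rmsd: float
    n_used: int


def kabsch(model_coords: np.ndarray, native_coords: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of paired coordinates.

    Returns the proper rotation R and translation t minimising
    ``|| (R @ model + t) - native ||``; reflections are never returned.
    """
    P = np.asarray(model_coords, dtype=float)
    Q = np.asarray(native_coords, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("need matching N x 3 coordinate arrays")
    if P.shape[0] < 3:
        raise ValueError("need at least 3 paired coordinates")
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    diff = (P @ R.T + t) - Q
    rmsd = float(np.sqrt((diff ** 2).sum() / P.shape[0]))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd,
                               n_used=P.shape[0])


def tm_d0(length: int) -> float:
    """TM-score distance scale d0 for a native of the given length."""
    return max(1.24 * (length - 15) ** (1.0 / 3.0) - 1.8, 0.5) if length > 15 else 0.5


def _score_from_superposition(R, t, model, native, d0, L):
    d = np.linalg.norm(model @ R.T + t - native, axis=1)
    return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / L), d


def tm_score(model: ProteinStructure, native: ProteinStructure,
             max_iter: int = 20) -> float:
    """TM-score of a (possibly partial) model against the native structure.

    The model must be indexed on the native residue numbering; unplaced
    residues carry NaN coordinates and count against the score through the
    native-length normalisation.
    """
    if len(model) != len(native):
        raise ValueError("model must be indexed on the native residue numbering")
    L = len(native)
    placed = model.placed_mask
    idx = np.flatnonzero(placed)
    if idx.size < 3:
        raise ValueError("need at least 3 placed model residues")
    mc = model.ca[idx]
    nc = native.ca[idx]
    d0 = tm_d0(L)
    n = idx.size
    frag_lens = sorted({n, max(n // 2, 4), max(n // 4, 4), 4}, reverse=True)
    stride = max(1, n // 10)
    best = 0.0
    for fl in frag_lens:
        if fl > n:
            continue
        for start in range(0, n - fl + 1, stride):
            sel = np.arange(start, start + fl)
            prev_sel = None
            for _ in range(max_iter):
                sup = kabsch(mc[sel], nc[sel])
                score, d = _score_from_superposition(sup.rotation, sup.translation,
                                                     mc, nc, d0, L)
                if score > best:
                    best = score
                # re-superpose on residues currently within the cutoff,
                # relaxing the cutoff until at least 3 qualify
                cut = d0
                new_sel = np.flatnonzero(d < cut)
                while new_sel.size < 3:
                    cut += 0.5
                    new_sel = np.flatnonzero(d < cut)
                if prev_sel is not None and np.array_equal(new_sel, prev_sel):
                    break
                prev_sel = sel = new_sel
    return best


def correct_fold(tm: float) -> bool:
    """True when TM-score > 0.5 (strict): same overall fold as the native."""
    return tm > 0.5
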