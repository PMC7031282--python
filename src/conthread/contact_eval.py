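"""Quality measures for predicted contact maps.

Five measures are computed for a predicted map against the native map:
precision, coverage, mean false-positive error, spread, and the Matthews
correlation coefficient (MCC).  The confusion matrix is taken over the
universe of residue pairs at sequence separation ``j - i >= sep_min``
(the same separation filter applied to predictions, so counts stay
commensurate).

Precision alone rewards sparse, cherry-picked predictions; MCC balances
true/false positives and negatives and is the headline measure, binned as
high (MCC >= 0.5), twilight (0.35 <= MCC < 0.5) and low (MCC < 0.35).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .contact_io import ContactMap, ProteinStructure, filter_map, native_contact_map

__all__ = [
    "ConfusionCounts",
    "ContactEvalResult",
    "EvalParams",
    "pair_universe",
    "confusion",
    "precision",
    "coverage",
    "mean_fp_error",
    "spread",
    "mcc",
    "quality_bin",
    "evaluate_map",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def universe(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class EvalParams:
    p_min: float = 0.5
    sep_min: int = 6
    threshold: float = 8.0
    atom_mode: str = "CB"


@dataclass(frozen=True)
class ContactEvalResult:
    precision: float  # percent
    coverage: float  # percent
    mean_fp_error: float  # Angstrom
    spread: float  # index-space distance; NaN when undefined (no predictions)
    mcc: float
    counts: ConfusionCounts
    bin: str
    no_predicted_contacts: bool = False


def pair_universe(length: int, sep_min: int = 6) -> int:
    """Number of residue pairs i < j with j - i >= sep_min."""
    n = length - sep_min
    return n * (n + 1) // 2 if n > 0 else 0


def confusion(pred: ContactMap, native: ContactMap, sep_min: int = 6) -> ConfusionCounts:
    """Confusion counts of a predicted vs native map over the separation-
    filtered pair universe.  Both maps must already obey the separation
    filter and share the same length."""
    if pred.length != native.length:
        raise ValueError(f"length mismatch: {pred.length} vs {native.length}")
    p, n = pred.pairs, native.pairs
    tp = len(p & n)
    fp = len(p - n)
    fn = len(n - p)
    tn = pair_universe(pred.length, sep_min) - tp - fp - fn
    if tn < 0:
        raise ValueError("maps contain pairs below the stated sep_min")
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def precision(c: ConfusionCounts) -> float:
    """Percent of predicted contacts that are correct; 0 when nothing was
    predicted."""
    denom = c.tp + c.fp
    return 100.0 * c.tp / denom if denom > 0 else 0.0


def coverage(c: ConfusionCounts) -> float:
    """Percent of native contacts recovered (recall)."""
    n_c = c.tp + c.fn
    if n_c == 0:
        raise ValueError("coverage undefined: native map has no contacts")
    return 100.0 * c.tp / n_c


def mean_fp_error(pred: ContactMap, native_structure: ProteinStructure,
                  threshold: float = 8.0, sep_min: int = 6,
                  atom_mode: str | None = None) -> float:
    """Mean absolute distance excess |d_ij - threshold| over false-positive
    pairs; 0 when the prediction has no false positives."""
    mode = atom_mode or pred.atom_mode
    native = native_contact_map(native_structure, threshold=threshold,
                                sep_min=sep_min, atom_mode=mode)
    fps = pred.pairs - native.pairs
    if not fps:
        return 0.0
    coords = native_structure.coords(mode)
    err = 0.0
    for i, j in fps:
        d = float(np.linalg.norm(coords[i - 1] - coords[j - 1]))
        err += abs(d - threshold)
    return err / len(fps)


def spread(pred: ContactMap, native: ContactMap) -> float:
    """Mean, over native contacts, of the index-space Euclidean distance to
    the nearest predicted contact (canonical i < j representations)."""
    if not native.contacts:
        raise ValueError("spread undefined: native map has no contacts")
    if not pred.contacts:
        raise ValueError("spread undefined: prediction has no contacts")
    T = np.array(sorted(native.pairs), dtype=float)
    P = np.array(sorted(pred.pairs), dtype=float)
    return float(cdist(T, P).min(axis=1).mean())


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any denominator factor
    vanishes."""
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom == 0:
        return 0.0
    num = c.tp * c.tn - c.fp * c.fn
    return num / math.sqrt(denom)


def quality_bin(mcc_value: float, thresholds: tuple[float, float] = (0.35, 0.5)) -> str:
    """Bin an MCC value: high (>= 0.5), twilight ([0.35, 0.5)), low (< 0.35).

    Both lower bounds are inclusive for their bins.
    """
    lo, hi = thresholds
    if mcc_value >= hi:
        return "high"
    if mcc_value >= lo:
        return "twilight"
    return "low"


def evaluate_map(pred: ContactMap, native_structure: ProteinStructure,
                 params: EvalParams = EvalParams()) -> ContactEvalResult:
    """Filter a predicted map, derive the native map from coordinates, and
    compute all five quality measures plus the MCC quality bin.

    With an empty filtered prediction, spread is undefined and reported as
    NaN with ``no_predicted_contacts`` set.
    """
    if pred.length != len(native_structure):
        raise ValueError("prediction and native structure lengths differ")
    filtered = filter_map(pred, p_min=params.p_min, sep_min=params.sep_min)
    native = native_contact_map(native_structure, threshold=params.threshold,
                                sep_min=params.sep_min, atom_mode=params.atom_mode)
    counts = confusion(filtered, native, sep_min=params.sep_min)
    m = mcc(counts)
    empty = len(filtered.contacts) == 0
    return ContactEvalResult(
        precision=precision(counts),
        coverage=coverage(counts),
        mean_fp_error=mean_fp_error(filtered, native_structure,
                                    threshold=params.threshold,
                                    sep_min=params.sep_min,
                                    atom_mode=params.atom_mode),
        spread=float("nan") if empty else spread(filtered, native),
        mcc=m,
        counts=counts,
        bin=quality_bin(m),
        no_predicted_contacts=empty,
    )
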