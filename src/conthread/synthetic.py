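"""Synthetic proteins, template libraries and noise-controlled contact maps.

This module generates everything the threading analysis consumes, with
controlled statistical structure:

* compact single-domain C-alpha traces (self-avoiding walks biased toward
  a globular radius of gyration, 3.8 Angstrom virtual bonds);
* per-residue feature tracks derived from the generated geometry, with
  optional prediction-like corruption for the query side;
* template libraries containing partial-fold structural relatives that
  share a conserved core with the target but have a graded fraction of
  the fold re-drawn, plus decoys from other targets' folds;
* "predicted" contact maps built from the native map by keeping a chosen
  fraction of true contacts and adding exactly as many false positives
  as needed to hit a requested MCC, with per-source placement models
  (uniform near-neutral noise, or conserved-core true positives with
  clustered false-positive patches for coupling-analysis-like sources).

All randomness flows from a single benchmark seed through named
substreams, so regeneration from the same spec is bit-reproducible.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .contact_io import (
    AA1,
    ContactMap,
    FeatureTrack,
    ProteinStructure,
    hydropathy,
    native_contact_map,
    read_rr,
    read_structure,
    write_rr,
    write_structure,
)
from .threading import Template

__all__ = [
    "GenerationError",
    "BenchmarkSpec",
    "BenchmarkTarget",
    "BenchmarkBundle",
    "gen_structure",
    "gen_features",
    "perturb_template",
    "noisy_contact_map",
    "gen_benchmark",
    "write_bundle",
    "load_bundle",
]

_STEP = 3.8  # virtual C-alpha bond length, Angstrom
_MIN_NONADJ = 4.0  # excluded-volume distance for non-adjacent residues
_RG_COEFF, _RG_EXP = 2.2, 0.38  # globular radius-of-gyration scaling


class GenerationError(RuntimeError):
    pass


def child_seed(seed: int, *keys) -> int:
    """Deterministic named substream seed (kept below 2**31)."""
    tag = ":".join(str(k) for k in (seed, *keys))
    return zlib.crc32(tag.encode()) & 0x7FFFFFFF


# ---------------------------------------------------------------------------
# structures


def gen_structure(L: int, seed: int, max_restarts: int = 50,
                  structure_id: str | None = None) -> ProteinStructure:
    """Generate a compact self-avoiding C-alpha walk of length ``L``.

    Steps are exactly 3.8 Angstrom; non-adjacent residues stay at least
    4.0 Angstrom apart; a centroid pull keeps the running radius of
    gyration near the globular target 2.2 * L**0.38.  C-beta atoms are
    placed 1.5 Angstrom off the backbone (C-alpha copied for glycine).
    """
    if L < 20:
        raise ValueError("structures shorter than 20 residues are not generated")
    rng = np.random.default_rng(seed)
    coords = None
    for _ in range(max_restarts):
        coords = _try_walk(L, rng)
        if coords is not None:
            break
    if coords is None:
        raise GenerationError(
            f"could not grow a compact self-avoiding walk of length {L}")
    sequence = "".join(rng.choice(list(AA1), size=L))
    cb = _place_cb(coords, sequence)
    return ProteinStructure(id=structure_id or f"synth_L{L}_s{seed}",
                            sequence=sequence, ca=coords, cb=cb)


def _try_walk(L: int, rng: np.random.Generator) -> np.ndarray | None:
    coords = np.zeros((L, 3))
    coords[1] = _STEP * _unit(rng.normal(size=3))
    for i in range(2, L):
        centroid = coords[:i].mean(axis=0)
        rg = float(np.sqrt(((coords[:i] - centroid) ** 2).sum(axis=1).mean()))
        rg_target = _RG_COEFF * i ** _RG_EXP
        pull = np.clip(2.0 * (rg - rg_target) / rg_target, 0.0, 3.0)
        placed = False
        for _ in range(80):
            direction = rng.normal(size=3)
            cvec = centroid - coords[i - 1]
            cn = np.linalg.norm(cvec)
            if pull > 0 and cn > 1e-9:
                direction = direction + pull * cvec / cn
            cand = coords[i - 1] + _STEP * _unit(direction)
            d = np.linalg.norm(coords[: i - 1] - cand, axis=1)
            if d.size == 0 or d.min() >= _MIN_NONADJ:
                coords[i] = cand
                placed = True
                break
        if not placed:
            return None
    return coords


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 1e-12 else np.array([1.0, 0.0, 0.0])


def _place_cb(ca: np.ndarray, sequence: str) -> np.ndarray:
    """Pseudo C-beta 1.5 Angstrom along the local bisector away from the
    backbone; glycines keep the C-alpha position."""
    L = len(ca)
    cb = ca.copy()
    for i in range(L):
        if sequence[i] == "G":
            continue
        lo, hi = max(i - 1, 0), min(i + 1, L - 1)
        direction = ca[i] - (ca[lo] + ca[hi]) / 2.0
        if np.linalg.norm(direction) < 1e-9:
            direction = np.array([0.0, 0.0, 1.0])
        cb[i] = ca[i] + 1.5 * _unit(direction)
    return cb


# ---------------------------------------------------------------------------
# features


def _bend_angles(ca: np.ndarray) -> np.ndarray:
    """Pseudo bond angle at each interior residue, degrees."""
    L = len(ca)
    theta = np.full(L, 120.0)
    a = ca[:-2] - ca[1:-1]
    b = ca[2:] - ca[1:-1]
    cosang = (a * b).sum(axis=1) / (
        np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1))
    theta[1:-1] = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    theta[0], theta[-1] = theta[1], theta[-2]
    return theta


def _dihedral(p0, p1, p2, p3) -> float:
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - (b0 @ b1) * b1
    w = b2 - (b2 @ b1) * b1
    x = v @ w
    y = np.cross(b1, v) @ w
    return float(np.degrees(np.arctan2(y, x)))


def gen_features(s: ProteinStructure, seed: int,
                 seq_noise: float = 0.3, struct_noise: float = 0.4,
                 ss_flip: float = 0.0, sa_sigma: float = 0.0,
                 torsion_sigma: float = 0.0) -> FeatureTrack:
    """Derive a feature track from generated geometry.

    Secondary structure from pseudo bond angles (tight runs -> H, extended
    runs -> E, else C, with runs shorter than 3 coerced to C); solvent
    accessibility as the inverted rank of the 10-Angstrom contact number;
    torsions as virtual C-alpha dihedrals; profiles as one-hot sequence
    rows mixed with Dirichlet noise; hydropathy from the Kyte-Doolittle
    scale.

    ``ss_flip``, ``sa_sigma`` and ``torsion_sigma`` corrupt the
    structure-derived channels to emulate *predicted* features: in real
    threading the query side carries predictions (secondary structure at
    ~80% three-state accuracy, noisy accessibility and torsions) while
    template features are observed from known structures.
    """
    rng = np.random.default_rng(seed)
    L = len(s)
    ca = s.ca
    theta = _bend_angles(ca)
    raw = np.where(theta < 100.0, "H", np.where(theta >= 140.0, "E", "C"))
    ss = _smooth_ss(raw)
    # contact number -> inverted rank in [0, 1]
    d = np.linalg.norm(ca[:, None] - ca[None, :], axis=-1)
    near = (d < 10.0)
    for off in (-2, -1, 0, 1, 2):
        idx = np.arange(max(0, -off), min(L, L - off))
        near[idx, idx + off] = False
    cn = near.sum(axis=1)
    order = np.argsort(np.argsort(cn, kind="stable"), kind="stable")
    sa = 1.0 - order / max(L - 1, 1)
    phi = np.zeros(L)
    psi = np.zeros(L)
    for i in range(L):
        if 2 <= i <= L - 2:
            phi[i] = _dihedral(ca[i - 2], ca[i - 1], ca[i], ca[i + 1])
        if 1 <= i <= L - 3:
            psi[i] = _dihedral(ca[i - 1], ca[i], ca[i + 1], ca[i + 2])
    if ss_flip > 0:
        flip = rng.random(L) < ss_flip
        alt = rng.choice(list("HEC"), size=L)
        ss = np.where(flip, alt, ss)
    if sa_sigma > 0:
        sa = np.clip(sa + rng.normal(0.0, sa_sigma, size=L), 0.0, 1.0)
    if torsion_sigma > 0:
        phi = (phi + rng.normal(0.0, torsion_sigma, size=L) + 180.0) % 360.0 - 180.0
        psi = (psi + rng.normal(0.0, torsion_sigma, size=L) + 180.0) % 360.0 - 180.0
    aa_index = {a: k for k, a in enumerate(AA1)}
    onehot = np.zeros((L, 20))
    for i, a in enumerate(s.sequence):
        onehot[i, aa_index.get(a, 0)] = 1.0
    seq_profile = _mix(onehot, seq_noise, rng)
    struct_profile = _mix(onehot, struct_noise, rng)
    return FeatureTrack(ss=ss, sa=sa, phi=phi, psi=psi,
                        seq_profile=seq_profile, struct_profile=struct_profile,
                        hydro=hydropathy(s.sequence))


def _smooth_ss(raw: np.ndarray) -> np.ndarray:
    ss = raw.copy()
    L = len(ss)
    i = 0
    while i < L:
        j = i
        while j < L and ss[j] == ss[i]:
            j += 1
        if ss[i] != "C" and (j - i) < 3:
            ss[i:j] = "C"
        i = j
    return ss


def _mix(onehot: np.ndarray, alpha: float, rng: np.random.Generator) -> np.ndarray:
    noise = rng.dirichlet(np.full(20, 0.5), size=onehot.shape[0])
    prof = (1.0 - alpha) * onehot + alpha * noise
    return prof / prof.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# template perturbation


def perturb_template(s: ProteinStructure, sigma: float, frag_shuffle: float,
                     seed: int, target_identity: float | None = None,
                     template_id: str | None = None,
                     window_starts: tuple[int, ...] | None = None) -> ProteinStructure:
    """Derive a template of graded similarity from a parent structure.

    Adds isotropic Gaussian coordinate noise of scale ``sigma``; re-draws
    a ``frag_shuffle`` fraction of 8-residue windows as fresh random-walk
    segments; optionally mutates the sequence so that roughly
    ``target_identity`` of positions keep the parent residue.

    ``window_starts`` restricts which window start positions may be
    re-drawn (used to keep a conserved structural core intact across a
    family of related templates); by default any position is eligible.
    """
    if sigma < 0 or not (0.0 <= frag_shuffle < 1.0):
        raise ValueError("sigma must be >= 0 and frag_shuffle in [0, 1)")
    rng = np.random.default_rng(seed)
    L = len(s)
    ca = s.ca + (rng.normal(0.0, sigma, size=(L, 3)) if sigma > 0 else 0.0)
    n_win = int(round(frag_shuffle * L / 8.0))
    if n_win > 0:
        if window_starts is None:
            starts = rng.choice(max(L - 8, 1), size=n_win, replace=False)
        else:
            pool = np.asarray(window_starts)
            starts = rng.choice(pool, size=min(n_win, pool.size), replace=False)
        for st in sorted(starts):
            anchor = ca[st - 1] if st > 0 else ca[0]
            pos = anchor
            for k in range(st, min(st + 8, L)):
                pos = pos + _STEP * _unit(rng.normal(size=3))
                ca[k] = pos
    sequence = s.sequence
    if target_identity is not None:
        sequence = _mutate_to_identity(s.sequence, target_identity, rng)
    cb = _place_cb(ca, sequence)
    return ProteinStructure(id=template_id or f"{s.id}_perturbed",
                            sequence=sequence, ca=ca, cb=cb)


def _mutate_to_identity(parent: str, target: float,
                        rng: np.random.Generator) -> str:
    """Mutate random positions until alignment-measured identity reaches
    the target.

    Gapped alignment recovers spurious matches, so the measured identity
    sits above the unmutated fraction; mutating in small increments and
    re-measuring closes the loop.
    """
    from .threading import sequence_identity

    L = len(parent)
    seq = list(parent)
    unmutated = list(range(L))
    rng.shuffle(unmutated)
    n_mut = int(round((1.0 - target) * L))
    step = max(1, L // 50)
    for _ in range(60):
        while n_mut > 0 and unmutated:
            p = unmutated.pop()
            choices = [a for a in AA1 if a != seq[p]]
            seq[p] = choices[rng.integers(len(choices))]
            n_mut -= 1
        measured = sequence_identity(parent, "".join(seq))
        if measured <= 100.0 * target + 2.0 or not unmutated:
            break
        n_mut = step
    return "".join(seq)


# ---------------------------------------------------------------------------
# noise-controlled contact maps


def _mcc_counts(tp, fp, fn, tn):
    tp = np.asarray(tp, dtype=float)
    fp = np.asarray(fp, dtype=float)
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    num = tp * tn - fp * fn
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den > 0, num / np.sqrt(den), 0.0)
    return out


def noisy_contact_map(native: ContactMap, target_mcc: float, coverage: float,
                      seed: int, sep_min: int = 6,
                      mcc_tol: float = 0.02,
                      fp_clustered: bool = False,
                      tp_pool: set[tuple[int, int]] | None = None) -> ContactMap:
    """Build a synthetic "predicted" map hitting a requested MCC.

    ``round(coverage * N_c)`` native contacts are kept as true positives;
    the false-positive count is then found by integer search so the exact
    MCC over the separation-filtered pair universe is as close as possible
    to ``target_mcc``.  If no FP count at that coverage comes within
    ``mcc_tol``, the TP count is re-solved as well (note attached in
    ``meta``); if no (TP, FP) combination reaches the target, a
    GenerationError names the feasible MCC range.  Likelihoods are drawn
    uniformly from [0.5, 1] so the maps survive the standard filters.

    ``fp_clustered=False`` places false positives uniformly over the
    eligible non-contact pairs (neutral noise with a checkable
    mean-FP-error expectation).  ``fp_clustered=True`` grows them as
    small index-space patches around random anchors, emulating the
    correlated artifacts of coupling-based predictors, whose spurious
    couplings cluster into coherent-looking but wrong contact patches.

    ``tp_pool`` biases which native contacts become true positives: they
    are drawn from this subset first (topping up from the rest only when
    the pool is too small).  Coupling-analysis predictors recover the
    strongly coevolving conserved-core pairs, so their sparse true
    contacts concentrate there.
    """
    if not native.contacts:
        raise ValueError("native map is empty")
    if not (0.0 < target_mcc <= 1.0) or not (0.0 < coverage <= 1.0):
        raise ValueError("target_mcc and coverage must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    L = native.length
    nat_pairs = sorted(native.pairs)
    n_c = len(nat_pairs)
    ii, jj = np.triu_indices(L, k=sep_min)
    all_pairs = list(zip((ii + 1).tolist(), (jj + 1).tolist()))
    universe = len(all_pairs)
    noncontact = sorted(set(all_pairs) - set(nat_pairs))
    max_fp = len(noncontact)

    def best_fp(tp: int) -> tuple[int, float]:
        fn = n_c - tp
        fp_grid = np.arange(0, max_fp + 1)
        tn = universe - tp - fp_grid - fn
        vals = _mcc_counts(tp, fp_grid, fn, tn)
        k = int(np.argmin(np.abs(vals - target_mcc)))
        return k, float(vals[k])

    tp = int(round(coverage * n_c))
    tp = max(min(tp, n_c), 0)
    note = None
    fp, achieved = best_fp(tp) if tp > 0 else (0, 0.0)
    if abs(achieved - target_mcc) > mcc_tol:
        # re-solve coverage too: scan all TP counts for the closest MCC
        best = (tp, fp, achieved)
        for tp_try in range(1, n_c + 1):
            fp_try, val = best_fp(tp_try)
            if abs(val - target_mcc) < abs(best[2] - target_mcc):
                best = (tp_try, fp_try, val)
        tp, fp, achieved = best
        if abs(achieved - target_mcc) > mcc_tol:
            lo, hi = _feasible_mcc_range(n_c, universe, max_fp)
            raise GenerationError(
                f"MCC {target_mcc} unreachable (feasible range "
                f"[{lo:.3f}, {hi:.3f}] for this map)")
        note = (f"coverage re-solved from {coverage:.3f} to {tp / n_c:.3f} "
                f"to reach MCC {target_mcc}")
    if tp_pool is not None:
        pool_idx = np.array([k for k, p in enumerate(nat_pairs) if p in tp_pool],
                            dtype=int)
        rest_idx = np.array([k for k, p in enumerate(nat_pairs) if p not in tp_pool],
                            dtype=int)
        take_pool = min(tp, len(pool_idx))
        tp_idx = rng.choice(pool_idx, size=take_pool, replace=False)
        if take_pool < tp:
            extra = rng.choice(rest_idx, size=tp - take_pool, replace=False)
            tp_idx = np.concatenate([tp_idx, extra])
    else:
        tp_idx = rng.choice(n_c, size=tp, replace=False)
    if fp_clustered:
        fp_pairs = _clustered_fps(noncontact, fp, rng)
    else:
        fp_idx = rng.choice(max_fp, size=fp, replace=False)
        fp_pairs = [noncontact[k] for k in sorted(fp_idx.tolist())]
    triples = []
    for k in sorted(tp_idx.tolist()):
        i, j = nat_pairs[k]
        triples.append((i, j, float(rng.uniform(0.5, 1.0))))
    for i, j in fp_pairs:
        triples.append((i, j, float(rng.uniform(0.5, 1.0))))
    meta = {"target_mcc": target_mcc, "achieved_mcc": achieved,
            "tp": tp, "fp": fp, "coverage_used": tp / n_c}
    if note:
        meta["note"] = note
    return ContactMap.from_pairs(L, triples, atom_mode=native.atom_mode, meta=meta)


def _clustered_fps(noncontact: list[tuple[int, int]], fp: int,
                   rng: np.random.Generator,
                   patch_radius: int = 3) -> list[tuple[int, int]]:
    """Draw ``fp`` false positives as index-space patches: random anchors
    plus eligible neighbours within ``patch_radius`` in both indices."""
    pool = set(noncontact)
    chosen: list[tuple[int, int]] = []
    order = list(noncontact)
    while len(chosen) < fp and pool:
        ai, aj = order[int(rng.integers(len(order)))]
        if (ai, aj) not in pool:
            continue
        patch = [(i, j) for i in range(ai - patch_radius, ai + patch_radius + 1)
                 for j in range(aj - patch_radius, aj + patch_radius + 1)
                 if (i, j) in pool]
        patch.sort(key=lambda p: abs(p[0] - ai) + abs(p[1] - aj))
        take = patch[: min(fp - len(chosen), len(patch))]
        for p in take:
            pool.discard(p)
        chosen.extend(take)
    return chosen


def _feasible_mcc_range(n_c: int, universe: int, max_fp: int) -> tuple[float, float]:
    lo, hi = 1.0, -1.0
    for tp in range(0, n_c + 1):
        fn = n_c - tp
        fp_grid = np.arange(0, max_fp + 1)
        tn = universe - tp - fp_grid - fn
        vals = _mcc_counts(tp, fp_grid, fn, tn)
        lo = min(lo, float(vals.min()))
        hi = max(hi, float(vals.max()))
    return lo, hi


# ---------------------------------------------------------------------------
# benchmark bundles


@dataclass(frozen=True)
class BenchmarkSpec:
    """Study conditions for one synthetic benchmark run.

    Defaults give 20 targets of 60-120 residues and 30-template
    libraries.  Each library holds one partial-fold structural relative
    per similarity level — a fraction of the fold re-drawn as fresh walk
    segments on top of mild 1.5 Angstrom coordinate noise, spanning
    mostly-correct down to barely-related topologies — plus decoys from
    other targets' folds; every template is mutated to ~22% sequence
    identity so it survives the 30% close-homolog cut, and carries its
    own feature-quality level (emulating variable profile depth and
    template annotation quality).  The query's feature track carries
    prediction-like noise (secondary structure flipped at 20%, jittered
    accessibility and torsions); template features are observed.

    Predicted contact maps emulate the four predictor classes whose
    outputs real contact-assisted threading consumes, each at its
    characteristic (MCC, coverage) operating point: deep-learning-like
    (0.65, 0.60), meta-predictor-like (0.42, 0.34), sparse-inverse-
    covariance-like (0.24, 0.088) and direct-coupling-analysis-like
    (0.14, 0.032) — low MCC comes with sparse maps, as it does for the
    real methods.
    """

    n_targets: int = 30
    length_range: tuple[int, int] = (60, 120)
    library_size: int = 30
    similarity_levels: tuple[float, ...] = (0.08, 0.16, 0.24, 0.32, 0.40, 0.48)
    relatives_per_level: int = 1
    relative_sigma: float = 1.5
    variable_fraction: float = 0.5
    mcc_targets: tuple[float, ...] = (0.65, 0.42, 0.24, 0.14)
    coverage_targets: tuple[float, ...] = (0.60, 0.34, 0.088, 0.032)
    relative_identity: float = 0.22
    coupling_like: tuple[bool, ...] = (False, False, True, True)
    template_feature_noise: float = 0.1
    query_ss_flip: float = 0.2
    query_sa_sigma: float = 0.15
    query_torsion_sigma: float = 40.0
    seed: int = 0

    def __post_init__(self):
        if self.n_targets < 1 or self.library_size < 1:
            raise ValueError("counts must be >= 1")
        if not all(0.0 <= m <= 1.0 for m in self.mcc_targets):
            raise ValueError("mcc_targets must lie in [0, 1]")
        if len(self.coverage_targets) != len(self.mcc_targets):
            raise ValueError("coverage_targets must pair with mcc_targets")
        if len(self.coupling_like) != len(self.mcc_targets):
            raise ValueError("coupling_like must pair with mcc_targets")


@dataclass(frozen=True)
class BenchmarkTarget:
    id: str
    structure: ProteinStructure
    features: FeatureTrack
    native_map: ContactMap
    predicted: dict[str, ContactMap]
    library: list[Template]


@dataclass(frozen=True)
class BenchmarkBundle:
    spec: BenchmarkSpec
    targets: list[BenchmarkTarget]
    manifest: dict


def gen_benchmark(spec: BenchmarkSpec,
                  out_dir: str | Path | None = None) -> BenchmarkBundle:
    """Generate a full benchmark bundle (optionally written to disk).

    Each target gets: a native structure + features, its native contact
    map, one noisy predicted map per requested MCC, and a library mixing
    graded-similarity relatives of the target with decoys perturbed from
    other targets' folds.
    """
    seed = spec.seed
    rng_len = np.random.default_rng(child_seed(seed, "lengths"))
    lengths = rng_len.integers(spec.length_range[0], spec.length_range[1] + 1,
                               size=spec.n_targets)
    natives = []
    for t in range(spec.n_targets):
        tid = f"T{t:03d}"
        natives.append(gen_structure(int(lengths[t]),
                                     child_seed(seed, "target", tid),
                                     structure_id=tid))
    n_rel = spec.relatives_per_level * len(spec.similarity_levels)
    n_dec = max(0, spec.library_size - n_rel)
    targets = []
    for t, native in enumerate(natives):
        tid = native.id
        feats = gen_features(native, child_seed(seed, "feat", tid),
                             ss_flip=spec.query_ss_flip,
                             sa_sigma=spec.query_sa_sigma,
                             torsion_sigma=spec.query_torsion_sigma)
        nmap = native_contact_map(native)
        # conserved structural core: 8-residue blocks kept intact across
        # every relative; the complement ("variable" blocks) is what the
        # similarity levels re-draw.  Coupling-analysis-like maps draw
        # their sparse true contacts from core-core pairs.
        L = len(native)
        block_starts = np.arange(0, max(L - 8, 1), 8)
        core_rng = np.random.default_rng(child_seed(seed, "core", tid))
        n_var = max(1, int(round(spec.variable_fraction * len(block_starts))))
        var_blocks = core_rng.choice(len(block_starts), size=n_var, replace=False)
        var_starts = tuple(int(block_starts[b]) for b in sorted(var_blocks))
        core_mask = np.ones(L, dtype=bool)
        for st in var_starts:
            core_mask[st:st + 8] = False
        core_pairs = {(i, j) for (i, j) in nmap.pairs
                      if core_mask[i - 1] and core_mask[j - 1]}
        predicted = {}
        for m, cov, coup in zip(spec.mcc_targets, spec.coverage_targets,
                                spec.coupling_like):
            src = f"mcc{m:.2f}"
            predicted[src] = noisy_contact_map(
                nmap, m, cov, child_seed(seed, "map", tid, src),
                fp_clustered=coup,
                tp_pool=core_pairs if coup else None)
        # per-template feature-quality level: observed template features
        # vary in quality (profile depth, annotation errors) independently
        # of the fold itself
        corr_rng = np.random.default_rng(child_seed(seed, "tplnoise", tid))

        def template_features(ts: ProteinStructure, fseed: int) -> FeatureTrack:
            c = float(corr_rng.uniform(0.0, spec.template_feature_noise))
            return gen_features(ts, fseed, ss_flip=c, sa_sigma=c,
                                torsion_sigma=140.0 * c)

        library: list[Template] = []
        for lvl_i, frac in enumerate(spec.similarity_levels):
            for r in range(spec.relatives_per_level):
                tpl_id = f"{tid}_rel{lvl_i}{r}"
                ts = perturb_template(native, spec.relative_sigma, frac,
                                      child_seed(seed, "rel", tid, tpl_id),
                                      target_identity=spec.relative_identity,
                                      template_id=tpl_id,
                                      window_starts=var_starts)
                tf = template_features(
                    ts, child_seed(seed, "relfeat", tid, tpl_id))
                library.append(Template(id=tpl_id, structure=ts, features=tf))
        if spec.n_targets > 1:
            for d in range(n_dec):
                src_t = natives[(t + 1 + d % (spec.n_targets - 1)) % spec.n_targets]
                tpl_id = f"{tid}_dec{d}"
                ts = perturb_template(src_t, 1.0, 0.2,
                                      child_seed(seed, "dec", tid, tpl_id),
                                      target_identity=spec.relative_identity,
                                      template_id=tpl_id)
                tf = template_features(
                    ts, child_seed(seed, "decfeat", tid, tpl_id))
                library.append(Template(id=tpl_id, structure=ts, features=tf))
        targets.append(BenchmarkTarget(id=tid, structure=native, features=feats,
                                       native_map=nmap, predicted=predicted,
                                       library=library))
    manifest = _manifest(spec, targets)
    bundle = BenchmarkBundle(spec=spec, targets=targets, manifest=manifest)
    if out_dir is not None:
        write_bundle(bundle, out_dir)
    return bundle


def _manifest(spec: BenchmarkSpec, targets: list[BenchmarkTarget]) -> dict:
    return {
        "spec": {
            "n_targets": spec.n_targets,
            "length_range": list(spec.length_range),
            "library_size": spec.library_size,
            "similarity_levels": list(spec.similarity_levels),
            "relatives_per_level": spec.relatives_per_level,
            "relative_sigma": spec.relative_sigma,
            "mcc_targets": list(spec.mcc_targets),
            "coverage_targets": list(spec.coverage_targets),
            "relative_identity": spec.relative_identity,
            "coupling_like": list(spec.coupling_like),
            "variable_fraction": spec.variable_fraction,
            "template_feature_noise": spec.template_feature_noise,
            "query_ss_flip": spec.query_ss_flip,
            "query_sa_sigma": spec.query_sa_sigma,
            "query_torsion_sigma": spec.query_torsion_sigma,
            "seed": spec.seed,
        },
        "targets": [
            {
                "id": t.id,
                "length": len(t.structure),
                "n_native_contacts": len(t.native_map.contacts),
                "library": [tpl.id for tpl in t.library],
                "predicted": {
                    src: {"n_contacts": len(m.contacts), "meta": m.meta}
                    for src, m in sorted(t.predicted.items())
                },
            }
            for t in targets
        ],
    }


def write_bundle(bundle: BenchmarkBundle, out_dir: str | Path) -> None:
    out = Path(out_dir)
    for t in bundle.targets:
        tdir = out / "targets" / t.id
        (tdir / "library").mkdir(parents=True, exist_ok=True)
        write_structure(t.structure, tdir / "native.pdb")
        write_rr(t.native_map, tdir / "native.rr")
        (tdir / "features.json").write_text(
            json.dumps(t.features.to_dict(), sort_keys=True))
        for src, m in sorted(t.predicted.items()):
            write_rr(m, tdir / f"{src}.rr")
        for tpl in t.library:
            write_structure(tpl.structure, tdir / "library" / f"{tpl.id}.pdb")
            (tdir / "library" / f"{tpl.id}.json").write_text(
                json.dumps(tpl.features.to_dict(), sort_keys=True))
    (out / "manifest.json").write_text(
        json.dumps(bundle.manifest, sort_keys=True, indent=1))


def load_bundle(in_dir: str | Path) -> BenchmarkBundle:
    """Load a bundle previously written by ``write_bundle``.

    Coordinates round-trip at PDB precision (1e-3 Angstrom), so analyses on
    a loaded bundle can differ in the last digits from in-memory runs.
    """
    root = Path(in_dir)
    manifest = json.loads((root / "manifest.json").read_text())
    sp = manifest["spec"]
    for key in ("length_range", "similarity_levels", "mcc_targets",
                "coverage_targets", "coupling_like"):
        sp[key] = tuple(sp[key])
    spec = BenchmarkSpec(**sp)
    targets = []
    for tinfo in manifest["targets"]:
        tdir = root / "targets" / tinfo["id"]
        structure = read_structure(tdir / "native.pdb")
        structure = ProteinStructure(id=tinfo["id"], sequence=structure.sequence,
                                     ca=structure.ca, cb=structure.cb)
        L = len(structure)
        feats = FeatureTrack.from_dict(json.loads((tdir / "features.json").read_text()))
        nmap = read_rr(tdir / "native.rr", L)
        predicted = {src: read_rr(tdir / f"{src}.rr", L)
                     for src in tinfo["predicted"]}
        library = []
        for tpl_id in tinfo["library"]:
            ts = read_structure(tdir / "library" / f"{tpl_id}.pdb")
            ts = ProteinStructure(id=tpl_id, sequence=ts.sequence, ca=ts.ca, cb=ts.cb)
            tf = FeatureTrack.from_dict(
                json.loads((tdir / "library" / f"{tpl_id}.json").read_text()))
            library.append(Template(id=tpl_id, structure=ts, features=tf))
        targets.append(BenchmarkTarget(id=tinfo["id"], structure=structure,
                                       features=feats, native_map=nmap,
                                       predicted=predicted, library=library))
    return BenchmarkBundle(spec=spec, targets=targets, manifest=manifest)
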