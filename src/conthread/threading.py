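"""Contact-assisted and contact-free ("pure") protein threading.

A query is aligned to every template in a library by Needleman-Wunsch
global alignment with affine gaps over a composite per-residue-pair
scoring function (sequence profile, structure profile, secondary
structure, solvent accessibility, torsion angles and hydropathy match).
Raw alignment scores are normalised by query length and standardised to
Z-scores over the library.  In assisted mode a contact-map-overlap score
between the query's predicted contact map and each template's native map
is fused additively: ``final = z + w_cmo * cmo``.  The best-scoring
template's aligned C-alpha coordinates are copied onto the query indexing
to build the threaded model, with no refinement.

Close homologs (global-alignment sequence identity above 30%) are
excluded from the library before ranking so the task stays a remote
homology problem.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._align import global_align
from .cmo import cmo_score_profiles, contact_pattern_profile
from .contact_io import ContactMap, FeatureTrack, ProteinStructure, native_contact_map

__all__ = [
    "FeatureWeights",
    "ThreadingConfig",
    "Template",
    "Query",
    "Alignment",
    "TemplateScore",
    "ThreadingResult",
    "pair_score",
    "similarity_matrix",
    "align",
    "zscores",
    "final_score",
    "sequence_identity",
    "filter_homologs",
    "rank_templates",
    "build_model",
]

_SS_CODE = {"H": 0, "E": 1, "C": 2}
_HYDRO_RANGE = 9.0  # Kyte-Doolittle span, -4.5 .. 4.5


@dataclass(frozen=True)
class FeatureWeights:
    prof: float = 1.0
    struct_prof: float = 1.0
    ss: float = 1.0
    sa: float = 1.0
    torsion: float = 1.0
    hydro: float = 1.0


@dataclass(frozen=True)
class ThreadingConfig:
    weights: FeatureWeights = FeatureWeights()
    gap_open: float = -7.0
    gap_ext: float = -0.5
    w_cmo: float = 4.0
    cmo_width: int = 40
    cmo_blur: float = 1.0
    cmo_gap_open: float = -0.1
    cmo_gap_ext: float = -0.01
    max_identity: float = 30.0
    p_min: float = 0.5
    sep_min: int = 6
    threshold: float = 8.0
    atom_mode: str = "CB"


@dataclass(frozen=True)
class Template:
    id: str
    structure: ProteinStructure
    features: FeatureTrack

    @property
    def sequence(self) -> str:
        return self.structure.sequence


@dataclass(frozen=True)
class Query:
    id: str
    sequence: str
    features: FeatureTrack
    predicted_map: ContactMap | None = None


@dataclass(frozen=True)
class Alignment:
    """Query-template aligned pairs, 1-based, strictly increasing in both."""

    pairs: tuple[tuple[int, int], ...]
    raw_score: float
    gaps: int


@dataclass(frozen=True)
class TemplateScore:
    template_id: str
    raw: float
    z: float
    cmo: float | None
    final: float


@dataclass(frozen=True)
class ThreadingResult:
    ranking: tuple[TemplateScore, ...]
    best: str
    alignment: Alignment
    model: ProteinStructure


def pair_score(qf: FeatureTrack, i: int, tf: FeatureTrack, j: int,
               w: FeatureWeights = FeatureWeights()) -> float:
    """Composite match score between query residue ``i`` and template
    residue ``j`` (both 0-based row indices into the feature tracks)."""
    s = w.prof * float(qf.seq_profile[i] @ tf.seq_profile[j])
    s += w.struct_prof * float(qf.struct_profile[i] @ tf.struct_profile[j])
    s += w.ss * (1.0 if qf.ss[i] == tf.ss[j] else 0.0)
    s += w.sa * (1.0 - abs(float(qf.sa[i]) - float(tf.sa[j])))
    dphi = np.deg2rad(qf.phi[i] - tf.phi[j])
    dpsi = np.deg2rad(qf.psi[i] - tf.psi[j])
    s += w.torsion * float(np.cos(dphi) + np.cos(dpsi)) / 2.0
    s += w.hydro * (1.0 - abs(float(qf.hydro[i]) - float(tf.hydro[j])) / _HYDRO_RANGE)
    return s


def similarity_matrix(qf: FeatureTrack, tf: FeatureTrack,
                      w: FeatureWeights = FeatureWeights()) -> np.ndarray:
    """Vectorised Lq x Lt matrix of pair_score values."""
    S = w.prof * (qf.seq_profile @ tf.seq_profile.T)
    S += w.struct_prof * (qf.struct_profile @ tf.struct_profile.T)
    S += w.ss * (qf.ss[:, None] == tf.ss[None, :]).astype(float)
    S += w.sa * (1.0 - np.abs(qf.sa[:, None] - tf.sa[None, :]))
    dphi = np.deg2rad(qf.phi[:, None] - tf.phi[None, :])
    dpsi = np.deg2rad(qf.psi[:, None] - tf.psi[None, :])
    S += w.torsion * (np.cos(dphi) + np.cos(dpsi)) / 2.0
    S += w.hydro * (1.0 - np.abs(qf.hydro[:, None] - tf.hydro[None, :]) / _HYDRO_RANGE)
    return S


def align(query: FeatureTrack, template: FeatureTrack,
          w: FeatureWeights = FeatureWeights(),
          gap_open: float = -7.0, gap_ext: float = -0.5) -> Alignment:
    """Optimal global query-template alignment under the composite score."""
    S = similarity_matrix(query, template, w)
    score, pairs0 = global_align(S, gap_open, gap_ext)
    pairs = tuple((i + 1, j + 1) for i, j in pairs0)
    gaps = (len(query) - len(pairs)) + (len(template) - len(pairs))
    return Alignment(pairs=pairs, raw_score=score, gaps=gaps)


def zscores(raws: list[float], lengths: list[int]) -> np.ndarray:
    """Length-normalise raw alignment scores and standardise over the
    library (population standard deviation).

    With fewer than 2 templates or zero dispersion, all Z-scores are 0
    (with a warning): ranking is then uninformative but well defined.
    """
    x = np.asarray(raws, dtype=float) / np.asarray(lengths, dtype=float)
    if x.size < 2:
        warnings.warn("fewer than 2 templates: Z-scores set to 0")
        return np.zeros_like(x)
    sd = x.std()  # population sd
    if sd == 0:
        warnings.warn("zero dispersion of alignment scores: Z-scores set to 0")
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def final_score(z: float, cmo: float | None, w_cmo: float = 4.0) -> float:
    """Fuse Z-score and contact-map overlap: ``z + w_cmo * cmo``; plain
    ``z`` when no overlap is available (pure threading)."""
    if cmo is None:
        return z
    if not (0.0 <= cmo <= 1.0):
        raise ValueError(f"cmo must lie in [0,1], got {cmo}")
    return z + w_cmo * cmo


def sequence_identity(a: str, b: str) -> float:
    """Global-alignment sequence identity in percent.

    Identities divided by aligned length, where aligned length counts the
    matched columns plus internal gap columns (terminal overhangs are not
    counted).
    """
    if not a or not b:
        return 0.0
    A = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
    B = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    S = np.where(A[:, None] == B[None, :], 2.0, -1.0)
    _, pairs = global_align(S, gap_open=-3.0, gap_ext=-0.5)
    if not pairs:
        return 0.0
    ident = sum(1 for i, j in pairs if a[i] == b[j])
    (fi, fj), (li, lj) = pairs[0], pairs[-1]
    n = len(pairs)
    internal_gaps = (li - fi + 1 - n) + (lj - fj + 1 - n)
    return 100.0 * ident / (n + internal_gaps)


def filter_homologs(library: list[Template], query_seq: str,
                    max_identity: float = 30.0) -> list[Template]:
    """Drop templates whose sequence identity to the query exceeds
    ``max_identity`` percent (the boundary itself is kept)."""
    return [t for t in library
            if sequence_identity(query_seq, t.sequence) <= max_identity]


def build_model(query_len: int, template: ProteinStructure, a: Alignment,
                query_sequence: str | None = None,
                model_id: str = "model") -> ProteinStructure:
    """Copy aligned template C-alpha coordinates onto the query indexing.

    Unaligned query positions get NaN coordinates (missing); no refinement
    is performed.
    """
    ca = np.full((query_len, 3), np.nan)
    for qi, ti in a.pairs:
        if not (1 <= qi <= query_len and 1 <= ti <= len(template)):
            raise ValueError(f"alignment pair ({qi},{ti}) out of bounds")
        ca[qi - 1] = template.ca[ti - 1]
    if not a.pairs:
        warnings.warn("empty alignment: model has no placed coordinates")
    seq = query_sequence if query_sequence is not None else "X" * query_len
    return ProteinStructure(id=model_id, sequence=seq, ca=ca)


def rank_templates(query: Query, library: list[Template], mode: str = "pure",
                   config: ThreadingConfig = ThreadingConfig(),
                   cache: dict | None = None) -> ThreadingResult:
    """Thread a query through a (homolog-filtered) template library.

    Pure mode ranks by Z-score alone; assisted mode additionally scores the
    contact-map overlap between the query's filtered predicted map and each
    template's native map and fuses it into the final score.  Ties in the
    final score break lexicographically by template id.  An optional
    ``cache`` dict reuses alignments and template spectral profiles across
    repeated calls on the same library.
    """
    if mode not in ("pure", "assisted"):
        raise ValueError(f"unknown mode {mode!r}")
    if not library:
        raise ValueError("no templates to rank (library empty after filtering)")
    if mode == "assisted" and query.predicted_map is None:
        raise ValueError("assisted mode requires a predicted contact map")
    cache = cache if cache is not None else {}
    aligns = cache.setdefault("alignments", {})
    for t in library:
        if t.id not in aligns:
            aligns[t.id] = align(query.features, t.features, config.weights,
                                 config.gap_open, config.gap_ext)
    qlen = len(query.features)
    raws = [aligns[t.id].raw_score for t in library]
    z = zscores(raws, [qlen] * len(library))
    cmos: list[float | None] = [None] * len(library)
    if mode == "assisted":
        from .contact_io import filter_map  # local import to avoid cycle noise

        pred = filter_map(query.predicted_map, p_min=config.p_min,
                          sep_min=config.sep_min)
        if pred.contacts:
            qprof = contact_pattern_profile(pred, config.cmo_width,
                                            config.cmo_blur)
            tprofs = cache.setdefault("template_profiles", {})
            for idx, t in enumerate(library):
                if t.id not in tprofs:
                    tmap = native_contact_map(
                        t.structure, threshold=config.threshold,
                        sep_min=config.sep_min, atom_mode=config.atom_mode)
                    tprofs[t.id] = (contact_pattern_profile(
                        tmap, config.cmo_width, config.cmo_blur)
                        if tmap.contacts else None)
                tp = tprofs[t.id]
                cmos[idx] = 0.0 if tp is None else cmo_score_profiles(
                    qprof, tp, config.cmo_gap_open, config.cmo_gap_ext)
        else:
            warnings.warn("predicted map empty after filtering; "
                          "assisted ranking falls back to pure scores")
            cmos = [0.0] * len(library)
    scores = [
        TemplateScore(template_id=t.id, raw=raws[i], z=float(z[i]), cmo=cmos[i],
                      final=final_score(float(z[i]), cmos[i], config.w_cmo))
        for i, t in enumerate(library)
    ]
    ranking = tuple(sorted(scores, key=lambda s: (-s.final, s.template_id)))
    best = ranking[0].template_id
    best_t = next(t for t in library if t.id == best)
    model = build_model(qlen, best_t.structure, aligns[best],
                        query_sequence=query.sequence,
                        model_id=f"{query.id}_on_{best}")
    return ThreadingResult(ranking=ranking, best=best,
                           alignment=aligns[best], model=model)
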