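# Methods

This note documents the models and procedures implemented in
`conthread`, the assumptions behind the synthetic data, and the design
choices made where the design was genuinely open. It states no result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Contact maps and their evaluation

A contact map over a chain of L residues is the set of canonical pairs
(i < j, 1-based) whose chosen atoms (Cβ by default, Cα for glycine) lie
within a distance threshold d = 8 Å. Predicted maps carry a contact
likelihood per pair and are cleaned with two standard filters before any
use: likelihood ≥ 0.5 (inclusive) and sequence separation j − i ≥ 6
(inclusive). Raw coupling scores that do not live on a probability scale
(direct-coupling analysis output) are first divided by their maximum.

Against the native map, a prediction is summarised by five measures.
Precision = TP/(TP+FP) and coverage = TP/N_c are reported as
percentages. Mean FP error is the mean of |d_ij − d| over false-positive
pairs, using the true inter-residue distance d_ij in the native
structure; for a genuine false positive d_ij > d, so this equals the
mean distance excess. Spread is the mean, over native contacts, of the
index-space Euclidean distance to the nearest predicted contact,
computed on canonical i < j representations so it is
representation-independent. MCC is the Matthews correlation coefficient
over the confusion matrix whose universe is all pairs at separation
≥ 6 — the same filter applied to predictions, so counts stay
commensurate. Conventions for degenerate inputs: MCC is 0 when any
marginal is 0; precision is 0 (flagged) when nothing was predicted;
spread is undefined (error, or NaN in composite results) when the
filtered prediction is empty; mean FP error is 0 when there are no false
positives. Quality bins: high (MCC ≥ 0.5), twilight ([0.35, 0.5)), low
(< 0.35), both lower boundaries inclusive.

Per-target metrics are computed and averaged per target; pooled-count
aggregation would weight long proteins more heavily and is not used.

## Contact-map overlap (CMO)

`cmo_score` compares two maps of possibly different lengths and returns
a similarity in [0, 1]. Each residue is described by its local contact
pattern: the row of the Gaussian-blurred (σ = 1 index unit) dense
contact matrix restricted to a diagonal band |j − i| ≤ 40, indexed by
sequence offset. Two residues from different maps are similar when they
see contact density at similar offsets; the blur tolerates contacts
slipping a residue or two, or crossing the 8 Å threshold under small
coordinate changes. The two profile stacks are aligned globally
(Needleman–Wunsch, affine gaps, open −0.1 / extend −0.01 — nearly free,
so length differences and terminal extensions are absorbed), and the raw
score S(A,B) is normalised as max(0, S(A,B)) / √(S(A,A)·S(B,B)) and
clipped to [0, 1]. The score is exactly symmetric (both argument orders
are evaluated and the max taken; they are mathematically equal) and
exactly 1 for identical maps.

An eigendecomposition summary of the contact matrix
(`spectral_profile`: top-k eigenvectors scaled by √|λ|, signs fixed so
the largest-magnitude entry is non-negative) is provided as well, but it
is deliberately not the representation behind `cmo_score`. At native
contact density the mean degree of the contact graph is about 2 and its
adjacency spectrum is nearly degenerate (leading |λ| ≈ 5.7, 4.2, 3.8,
3.6, … with no gap), so eigenvectors rotate freely under small
perturbations of the structure; in development the eigenvector-profile
alignment could not recover even the identity correspondence between a
map and its mildly perturbed twin, whereas the contact-pattern profile
ranks a graded library of relatives almost perfectly when given a
high-quality map. The banded profile keeps every contract the spectral
design was meant to satisfy while actually discriminating.

## Threading

The engine scores a query–template residue pair as a weighted sum of six
channels: dot products of the L×20 sequence profiles and structure
profiles; a secondary-structure identity indicator over {H, E, C};
1 − |ΔSA| for relative solvent accessibility; (cos Δφ + cos Δψ)/2 for
torsions; and 1 − |Δh|/9 for Kyte–Doolittle hydropathy (range −4.5 to
4.5). All channel weights default to 1. Global alignment uses the Gotoh
three-state recursion with affine gaps (open −7, extend −0.5), allowing
gap-direction switches, with deterministic tie-breaking (match > gap in
template > gap in query). Raw scores are divided by query length and
standardised over the library with the population standard deviation
(Z-scores). Pure threading ranks by Z alone.

Assisted threading computes the CMO between the query's filtered
predicted map and each template's native map and ranks by
final = Z + w·CMO with w = 4 by default. The weight was set by the
behaviour of the fused score itself: CMO differences across a library
span roughly 0.1–0.4, so w = 4 is the scale at which contact agreement
can genuinely re-order templates rather than merely break Z ties —
which is the regime in which contact quality matters at all. Setting
w = 0 reproduces the pure ranking bit for bit (the tested control).
Ties in the final score break lexicographically by template id.

Templates with global-alignment sequence identity above 30% to the query
are excluded beforehand (identities / aligned columns including internal
gap columns; the 30% boundary itself is kept). The best template's
aligned Cα coordinates are copied onto the query numbering with no
refinement; unaligned positions are marked missing (NaN) and count
against the model in TM-score through the native-length normalisation.

The base alignment is single-pass; an iterative query–template
realignment is a natural extension point but is not implemented.

## Structure evaluation

Kabsch superposition (SVD with a proper-rotation correction) gives the
least-squares RMSD. TM-score is

  TM = max over superpositions of (1/L) Σ 1/(1 + (d_i/d0)²),
  d0 = max(1.24 (L−15)^⅓ − 1.8, 0.5),

normalised by the native length L, summing over placed model residues.
The maximisation seeds superpositions from sliding fragments of lengths
{n, n/2, n/4, 4} at stride n/10 over the placed residues, then iterates
"superpose on residues currently within d0 (cutoff relaxed in 0.5 Å
steps until ≥ 3 residues qualify)" until the inclusion set is stable,
keeping the best score seen. Because the full-length superposition is
among the seeds, the heuristic never scores below plain all-residue
superposition. TM > 0.5 (strict) is called a correct fold.

## Synthetic data: what it emulates and what it does not

`gen_structure` grows a self-avoiding Cα walk with exact 3.8 Å steps, a
4.0 Å excluded-volume radius for non-adjacent residues, and a centroid
pull engaged whenever the running radius of gyration exceeds the
globular target 2.2·L^0.38 Å. Cβ atoms sit 1.5 Å along the local
bisector; glycine keeps Cα. Feature tracks are derived from the
geometry: secondary structure from pseudo bond angles (< 100° → H,
≥ 140° → E, runs shorter than 3 coerced to C), solvent accessibility as
the inverted rank of the 10 Å contact number, torsions as virtual Cα
dihedrals, profiles as one-hot rows mixed with Dirichlet noise, and
hydropathy from the sequence.

The default benchmark (`BenchmarkSpec`) encodes the study conditions:

- **30 targets** of 60–120 residues (kept modest so a full benchmark
  regenerates and runs in well under a minute on one CPU; the generator
  itself supports 50–300).
- **Query features are predictions.** The query's SS labels are flipped
  at 20%, SA jittered (σ = 0.15) and torsions jittered (σ = 40°),
  emulating sequence-based predictors; template features are observed
  from their structures, with mild per-template quality heterogeneity
  (corruption level drawn uniformly from [0, 0.1]) standing in for
  variable profile depth and annotation quality. Without a noisy query
  side, feature-only threading is error-free on this synthetic family
  and contact assistance would have nothing to do.
- **Libraries of 30 templates per target**: one partial-fold relative
  per similarity level — a fraction (0.08 … 0.48) of the fold re-drawn
  as fresh 8-residue walk segments over mild σ = 1.5 Å noise — plus
  decoys perturbed from other targets' folds. All template sequences are
  mutated to ~22% identity (closed-loop against the package's own
  identity measure) so they survive the 30% homolog cut: the task is
  remote-homology recognition, not twin detection. Each target carries a
  conserved core (half of its 8-residue blocks, chosen per target) that
  every relative keeps intact; only the complementary "variable" blocks
  are ever re-drawn, mirroring how homologous families conserve a
  structural core and diverge in the periphery.
- **Four contact sources per target**, at the characteristic
  (MCC, coverage) operating points of the four predictor classes whose
  outputs contact-assisted threading consumes: deep-learning-like
  (0.65, 0.60), meta-predictor-like (0.42, 0.34),
  sparse-inverse-covariance-like (0.24, 0.088) and
  direct-coupling-analysis-like (0.14, 0.032). Low MCC co-occurs with
  sparsity, as it does for the real predictor classes. The two
  coupling-analysis-like sources additionally (i) draw their true
  positives from conserved-core contacts — the strongly coevolving
  pairs such methods actually recover, which are shared by every related
  template and therefore carry no ranking information — and (ii) place
  their false positives as clustered index-space patches (radius 3
  around random anchors), emulating correlated coupling artifacts. The
  dense sources keep uniformly placed false positives, which are
  self-averaging and nearly neutral for ranking. These two placement
  models are the crux of the study design: uniformly placed errors at
  any density turned out to be harmless to template selection, so a
  benchmark built only from them cannot exhibit the degradation regime
  at all.

`noisy_contact_map` hits a requested MCC exactly by integer search: the
true-positive count is fixed by the requested coverage, and the
false-positive count is scanned for the closest exact MCC over the
separation-filtered pair universe; if no count lands within ±0.02 the
coverage is re-solved too (noted in the map's metadata), and if no
(TP, FP) combination can reach the target the generator raises an error
naming the feasible MCC range. Likelihoods are drawn from [0.5, 1] so
generated maps pass the standard filters unchanged.

All randomness flows from the benchmark seed through named CRC-derived
substreams; regeneration from the same spec is bit-reproducible, and the
record TSVs written by two independent runs are byte-identical.

What the synthetic family does *not* emulate: real backbone geometry
(Ramachandran statistics, side chains), predictor-specific error modes
beyond the coarse placement models above, multi-domain architecture, and
real sequence–structure covariation (profiles are one-hot plus noise).
Consequently, passing benchmarks here demonstrate the *mechanics* of the
quality–performance interdependence — that the same pipeline is helped
by dense, accurate maps and hurt by sparse, artifact-laden ones — not
predictive performance on real proteins.

## The analysis

For every (target × contact source) the benchmark homolog-filters the
library, runs pure and assisted threading (sharing alignments and
template contact profiles, so the modes differ only in the fused CMO
term), TM-scores both top models against the native, and records
ΔTM = TM_assisted − TM_pure together with the map's measured MCC.
Records are binned by MCC (thresholds 0.35 / 0.5) and summarised as
percentages improved (ΔTM > 0), degraded (ΔTM < 0) and unchanged
(|ΔTM| ≤ 1e-9; the explicit band keeps numerical noise out of the
directional counts). Length bins (<100, 100–150, >150) are reported as
well. Per contact source the analysis reports mean TM, the correct-fold
rate, and a two-sided one-sample t-test (sample SD, n−1 df) on the
paired deltas against zero; degenerate dispersion returns p = 1 for
all-zero deltas and p = 0 (with a warning) for identical non-zero ones.
The t-test p-values are reported, never asserted: the directional claims
are about counts and means.

`scripts/acceptance.py --seed S --out f.json` regenerates the default
benchmark at seed S and writes the headline quantities; the test suite
asserts the directional phenomenon on the default spec and bitwise
determinism of a repeated run.

## Known limitations

- The CMO weight (w = 4) and the generator's noise levels were fixed
  once for the default study conditions; other regimes (very large
  libraries, much longer chains) may need different scales.
- TM-score uses this package's own seed-fragment heuristic; it matches
  the published formula but is not guaranteed to find the global optimum
  superposition in pathological cases (it is bounded below by the
  all-residue superposition).
- The threading alignment is single-pass; no alignment-level use of
  contacts is made (contacts act on template *selection* only), so
  alignment errors are not correctable by good maps in this design.
- PDB round-trips quantise coordinates to 1e-3 Å; analyses on a bundle
  re-loaded from disk can differ in the last digits from in-memory runs
  (the determinism guarantee applies to each path separately).
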