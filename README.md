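# conthread

Contact-assisted protein threading, and the machinery to study how the
quality of a predicted residue–residue contact map governs how much the
contacts actually help.

Template-based ("threading") structure prediction aligns a query protein's
sequence and predicted features onto known template structures and copies
the aligned coordinates. Predicted contact maps — binary symmetric matrices
marking residue pairs whose Cβ (Cα for glycine) atoms lie within 8 Å —
can be fused into template selection through a contact-map-overlap (CMO)
score. But predicted maps range from excellent to nearly useless, and a
threading pipeline that trusts a bad map can end up *worse* than its
contact-free control. This package implements the full loop for studying
that trade-off on synthetic single-domain proteins, so every experiment is
self-contained and reproducible from a seed:

- **`contact_io`** — CASP RR contact files, PDB Cα/Cβ traces, native map
  extraction, and the standard filters (likelihood ≥ 0.5, sequence
  separation ≥ 6).
- **`contact_eval`** — the five map-quality measures: precision, coverage,
  mean false-positive error, spread, and the Matthews correlation
  coefficient

  MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

  with quality bins high (MCC ≥ 0.5), twilight (0.35 ≤ MCC < 0.5) and
  low (MCC < 0.35).
- **`cmo`** — an alignment-free contact-map-overlap score in [0, 1]
  between maps of possibly different lengths (blurred contact-pattern
  profiles aligned by Needleman–Wunsch, geometrically self-normalised).
- **`threading`** — Needleman–Wunsch global alignment with affine gaps
  over a composite scoring function (sequence and structure profiles,
  secondary structure, solvent accessibility, torsions, hydropathy),
  Z-score ranking over the template library, homolog exclusion
  (sequence identity > 30%), optional CMO fusion
  (final = Z + w·CMO), and coordinate-copy model building.
- **`structure_eval`** — Kabsch superposition RMSD and TM-score
  (d₀ = 1.24·(L−15)^⅓ − 1.8, floored at 0.5 Å; TM > 0.5 ⇒ correct fold).
- **`synthetic`** — generators for compact Cα traces, feature tracks,
  template libraries of graded similarity, and "predicted" maps tuned by
  integer search to hit a requested MCC at a requested coverage.
- **`analysis`** — the pure-vs-assisted benchmark: per (target × contact
  source) TM-score deltas, MCC-binned improvement/degradation
  percentages, and one-sample t-tests on the paired differences.

## Worked example

```python
from conthread import (BenchmarkSpec, gen_benchmark, gen_structure,
                       native_contact_map, noisy_contact_map, evaluate_map,
                       run_benchmark, summarize_bins)

native = gen_structure(80, seed=11)
nmap = native_contact_map(native)          # 8 A, C-beta, |i-j| >= 6
pred = noisy_contact_map(nmap, target_mcc=0.5, coverage=0.6, seed=1)
res = evaluate_map(pred, native)
print(f"precision {res.precision:.1f}%  coverage {res.coverage:.1f}%  "
      f"mean FP error {res.mean_fp_error:.2f} A  spread {res.spread:.2f}  "
      f"MCC {res.mcc:.3f}  bin {res.bin}")

records = run_benchmark(gen_benchmark(BenchmarkSpec(seed=1)))
summary = summarize_bins(records)
print(f"pure threading: mean TM {summary.pure_mean_tm:.3f}, "
      f"correct fold {summary.pure_pct_correct_fold:.1f}%")
for b in summary.bins:
    print(f"{b.bin:9s} n={b.n:3d}  improved {b.pct_improved:5.1f}%  "
          f"degraded {b.pct_degraded:5.1f}%  unchanged {b.pct_unchanged:5.1f}%")
```

prints

```
precision 46.6%  coverage 59.9%  mean FP error 12.38 A  spread 0.61  MCC 0.500  bin high
pure threading: mean TM 0.602, correct fold 93.3%
high      n= 30  improved  30.0%  degraded   0.0%  unchanged  70.0%
twilight  n= 30  improved  26.7%  degraded   6.7%  unchanged  66.7%
low       n= 60  improved  10.0%  degraded  18.3%  unchanged  71.7%
```

The first line evaluates one synthetic "prediction" built to hit MCC 0.5
at 60% coverage: the generator trades precision for coverage exactly as
the integer search dictates, and the map lands on the high-quality
boundary. The benchmark lines show the study's central phenomenon:
contact maps in the high-MCC bin improve the top-ranked model's TM-score
in 30% of cases and never degrade it, while low-MCC maps (sparse,
artifact-laden) degrade threading almost twice as often as they help.
The twilight bin sits in between.

A thin CLI mirrors the library: `conthread eval-map`, `conthread cmo`,
`conthread tmscore`, `conthread thread`, `conthread gen`,
`conthread benchmark` (see `--help` on each).

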