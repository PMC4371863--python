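# riboqms

Quantitative stable-isotope mass-spectrometry analysis of bacterial 30S
ribosome assembly, as a tested, reusable Python pipeline.

## The problem

When assembly factors of the *E. coli* small ribosomal subunit are deleted,
immature 30S particles accumulate in sucrose-gradient fractions.  Three
desk-side measurements characterize those intermediates:

1. **R-protein occupancy profiling.**  Cells grown in 15N media are mixed
   with a fixed spike of fully 15N-labeled ribosomes, so every tryptic
   peptide appears as a pair (or triple) of isotope envelopes.  The relative
   abundance of each of the 20 small-subunit proteins (S2–S21) per gradient
   fraction is the amplitude ratio ¹⁴N/(¹⁴N + ¹⁵N), normalized to the
   primary binder S4.  Hierarchical clustering of the resulting profiles
   (Euclidean distance, average linkage) recovers the tiers of the Nomura
   binding-dependency map.
2. **Pulse-labeling kinetics.**  After a shift to 15N media, the fraction
   of newly synthesized copies of a protein follows

   f_L(t) = 1 + P·exp[−k·(1 + 1/P)·t] − (1 + P)·exp(−k·t)

   where *k* is the growth rate and *P*, the only free parameter, is the
   precursor pool size — the unassembled pool of that protein (free copies
   plus intermediates) as a fraction of the standing population.  As P → 0
   this converges to the maximum-labeling curve f_max(t) = 1 − exp(−k·t):
   depleted late binders ride f_max, abundant early binders (e.g. S4, with
   P ≈ 0.12 in a ΔrimP strain) lag it.
3. **RNase H accessibility.**  A DNA oligo annealed to the central
   pseudoknot region (16S positions 906–920) directs RNase H cleavage,
   splitting the 1542-nt 16S into ~900-nt (5′) and ~600-nt (3′) products;
   the mock-corrected fraction cleaved measures how exposed that region is
   in each strain's intermediates.

The package implements all three, plus average-linkage clustering of
pre-aligned EM class-average images with per-group particle bookkeeping,
and a seeded synthetic-data generator that produces every input with the
statistical structure the analysis assumes — so the full pipeline runs and
is testable without any raw data.

## Worked example

```python
import numpy as np
from riboqms import TimeCourse, fit_pool_size, expected_products, ANTI_PK
from riboqms.synthetic import simulate_timecourses

courses, truth = simulate_timecourses({"S4": 0.12, "S12": 0.0},
                                      noise_sigma=0.01, seed=42)
print(fit_pool_size(courses[0]).summary())

sizes = expected_products(ANTI_PK, 1542)
print(f"anti-PK products: 5' {sizes.nominal_5p} nt, 3' {sizes.nominal_3p} nt")
```

prints

```
Precursor pool size fit
=======================
protein:          S4
n observations:   4
growth rate k:    0.0115525 /min
pool size P:      0.114215  (11.42% of standing population)
residual SS:      0.000228677
converged:        True
anti-PK products: 5' 905 nt, 3' 622 nt
```

The S4 time course was simulated with a true pool size of 0.12 and 1%
Gaussian noise at pulse lengths 15/20/30/45 min; the single-parameter fit
recovers P = 0.114 — an 11% precursor pool, the signature of an abundant
early binder feeding accumulated intermediates.  The oligo arithmetic
reproduces the ~900/~600-nt cleavage products expected for the central
pseudoknot site.

The same analyses are exposed as a CLI mirroring the stage sequence:

```sh
riboqms simulate --outdir sim/
riboqms quantify sim/peaklists.tsv sim/proteome.fasta --out ratios.tsv
riboqms profiles ratios.tsv --out matrix.tsv
riboqms cluster matrix.tsv --out-prefix clust
riboqms kinetics sim/timecourses.tsv --out pools.tsv
riboqms rnaseh sim/lanes.csv --out cleaved.csv
```

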