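# Methods

This note documents the models, numerical choices and limitations behind
`riboqms`.  Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`; nothing is asserted from memory.

## Isotope envelopes under 15N metabolic labeling

A peptide's isotope envelope is computed as the convolution, over its
C/H/N/O/S atoms, of per-element isotope distributions.  Carbon, hydrogen,
oxygen and sulfur use IUPAC natural abundances; nitrogen's two-isotope
probabilities are `(1 − e, e)` where `e` is the 15N enrichment of the
growth medium.  `e = 0.00364` reproduces natural nitrogen, `e = 0.5`
models 50% 15N media (the true incorporation of such media is not exactly
0.5, so `e` is a per-experiment config parameter), and `e = 1.0` models
the fully labeled reference spike.  Residue formulas come from pyteomics'
standard table; the only fixed modification is carbamidomethyl-Cys
(+C2H3NO per cysteine, reflecting iodoacetamide alkylation during sample
preparation); there are no variable modifications.

Isotopologues are aggregated at nominal-mass resolution: one peak per
"extra neutron" count, positioned at the probability-weighted exact mass
of its isotopologues.  The convolution tracks probability and first mass
moment per bin (binary exponentiation over atom counts), which makes the
envelope centroid exactly the expected neutral mass — linear in `e` with
slope `nN·(m(¹⁵N) − m(¹⁴N))`, a property the tests assert to 1e-6 Da.
Note the physical consequence: adjacent peak spacing is ~1.0034 Th/z where
A+1 is ¹³C-dominated and ~0.9970 Th/z where ¹⁵N dominates, i.e. close to
but not exactly the free-neutron mass; tests allow a 15 mTh band.  Fine
isotopic structure within a nominal-mass peak is deliberately merged.
Peaks below 1e-4 relative intensity are truncated and the envelope
renormalized, matching detector dynamic range without biasing fits.
Tryptic digestion cleaves C-terminal to K/R except before proline; this
simple rule is implemented directly (the Expasy rule's extra exceptions
are not wanted here) and the zero-missed-cleavage peptides provably
partition the protein.

The test-suite oracle for all of this is an independent brute-force
enumeration of element isotope-count vectors with multinomial weights;
convolution and enumeration agree to < 1e-9 per peak for short peptides.

## Species-amplitude fitting

Each peptide/charge has three envelope designs — pre-pulse (natural N),
post-pulse (fractional enrichment) and reference spike (e = 1) — and the
observed peak list is modeled as their non-negative linear combination.
Design peaks closer than the m/z tolerance (default 15 ppm, configurable)
are merged into shared columns and the fit is flagged, since species then
share signal; observed peaks are matched to the nearest column within
tolerance, unmatched design columns count as observed zero, and peaks
outside the detection window (default 250–1300 m/z, mirroring the
instrument setting) are ignored.  Amplitudes are solved by NNLS
(scipy), chosen because species abundances cannot be negative and the
three envelopes overlap substantially at high enrichment.  Whether the
original analysis fitted a scalar per envelope or summed matched
intensities is not specified anywhere we could find; the NNLS contract is
this package's choice and is cross-checked in tests against a dense
grid-search minimizer of the same objective.

Signal-to-noise is defined as (largest amplitude × that envelope's maximum
intensity) / residual RMS — infinite for a perfect fit, zero when nothing
was fitted.  The default exclusion threshold `snr_min = 5` is a package
choice; the per-protein exclusion list (for proteins whose fits are
systematically poor, as S17 was in the original data) is config.

Three ratio modes reduce amplitudes to fractions in [0, 1]:
`relative_abundance = a_pre/(a_pre + a_ref)`,
`fraction_labeled = a_post/(a_pre + a_post)`,
`strain_ratio = a_post/(a_post + a_ref)`.  Protein-level rollup is the
median of surviving peptide ratios (robust to one bad peptide; count and
MAD retained), then each fraction's column is divided by the reference
protein's value (S4 by default).  A protein with no surviving peptide in a
fraction is a missing ("gray box") entry; a fraction whose reference is
missing is flagged unnormalizable.

Because the measured quantity is the compressed ratio a/(a + a_ref) rather
than the molar abundance a, the synthetic truth tables carry both: the
zero-noise pipeline round trip is asserted against the expected normalized
ratio matrix, exact to 1e-6.

## Pulse-labeling kinetics

The fraction-labeled curve is
`fL(t) = 1 + P·exp[−k(1 + 1/P)t] − (1 + P)·exp(−kt)` with the continuous
limit `fmax(t) = 1 − exp(−kt)` at P = 0; the gap obeys the closed form
`fmax − fL = P·e^(−kt)(1 − e^(−kt/P)) ≥ 0`, asserted numerically on a
(t, P, k) grid.  The exponent is evaluated as `−kt − kt/P` so subnormal P
underflows to exp(−∞) rather than producing NaN at t = 0.

P is the only free parameter; k is supplied per experiment (no growth rate
is standard, so the default ln 2/60 min⁻¹ — a 60-minute doubling time — is
used in tests and simulations).  The fit minimizes squared error over
P ∈ [0, 10] (beyond ~10× the standing population the objective flattens
and larger pools are biologically meaningless) by bounded scalar
minimization restarted from the fixed grid {0.001, 0.01, 0.1, 1} with a
high-precision polish and an explicit P = 0 boundary evaluation, so fits
are deterministic.  Observed fL outside [0, 1] is clipped with a warning.
The convergence flag is false when the data are uninformative — all fL
within 1e-3 of zero, or all within 1e-3 of fmax (the latter still returns
the identified boundary value P = 0).

Group classification standardizes (P, abundance) points and runs
deterministic 2-means; a point farther than 3× (configurable) the
within-group RMS spread from *both* centers is an outlier.  Singleton
k-means clusters (an extreme point capturing its own center, which would
mask it from the outlier rule) are dropped and the clustering refitted
before spreads are computed.

## Clustering

One code path serves both uses: abundance profiles are clustered with
Euclidean distance and average linkage; pre-aligned class-average images
with correlation distance (1 − Pearson on flattened pixels) and average
linkage.  Missing abundance entries use pairwise-complete Euclidean
distances with the sum of squares rescaled by `n_total/n_complete`
(the mean-squared-per-coordinate convention of Gene Cluster-style tools),
avoiding imputation bias for undetected proteins.  Trees are scipy linkage
matrices; cuts are by group count or height, defaulting to half the
maximum merge height when unspecified.  Profiles are clustered
untransformed by default (a log switch is config since the original
convention is unstated).  Group bookkeeping is a dataset × group
cross-tabulation whose rows sum to dataset sizes (or to 1 in fractional
form).

## RNase H accessibility

Coordinates are 1-based inclusive throughout.  For an oligo occupying
(start, end) on an rRNA of length L, complete excision of the DNA:RNA
hybrid gives nominal products of `start − 1` and `L − end` nt; a
single-cut model brackets them with ranges `[start−1, end−1]` and
`[L−end, L−start]`, and any single cut's two products sum to L − 1.  The
default 16S length is 1542 nt (mature E. coli); with the anti-pseudoknot
oligo at 906–920 this yields 905 and 622 nt — the ~900/~600-nt gel bands.
Antisense validation compares the oligo's reverse complement (DNA→RNA)
against the target subsequence.  Fraction cleaved is
`max(products − mock, 0) / (corrected + intact)` per lane — mock (no-oligo)
subtraction never yields negative signal — with mean and sample SD (n−1)
over replicates.  Only the three modeled bands enter "total RNA"; real
gels may carry other species.

## Synthetic data

All generators are pure functions of (parameters, seed) and emit truth
tables.  Defaults define the simulated study conditions:

* **Occupancy truth**: 20 proteins S2–S21 in the four Nomura tiers
  (6 primary, 9 secondary, 3 tertiary-early, 2 tertiary-late), logistic
  onsets over 10 fractions with class midpoints 1/3/5/7 (width 0.7) so
  earlier binders saturate earlier; class pool sizes 0.12/0.06/0.02/0.005,
  anchored at the S4-like 12% pool for primaries.
* **Toy proteome**: synthetic sequences, not real r-protein sequences.
  Each protein carries one quantifiable tryptic peptide whose envelopes
  occupy a private ~38 Th slot of the detection window — a stand-in for
  the chromatographic separation the simulator does not model, verified
  collision-free at twice the matching tolerance.  Construction is
  deterministic (fixed internal seed).
* **Spectra**: species amplitudes (true abundance, optional post-pulse,
  1.0 reference); additive Gaussian noise scaled to the fraction's maximum
  peak, clipped at zero; peaks outside 250–1300 m/z dropped.  No
  chromatography, missed identification, or Poisson/shot noise.
* **Time courses**: model value + N(0, σ²), clipped to [0, 1], at pulse
  lengths 15/20/30/45 min.
* **Gel lanes**: intact/product/mock bands whose corrected fraction equals
  truth in expectation; additive Gaussian noise per band.
* **Class averages**: five 32×32 archetypes (body-only, detached head,
  angled head, near-mature, mature; max intensity 1) plus pixel Gaussian
  noise.  No projection physics or alignment errors — passing clustering
  tests show metric/linkage correctness, not robustness to real EM noise.

Because the generators are idealized, passing tests demonstrate the
correctness of the arithmetic and the estimators under their stated
assumptions; they do not demonstrate robustness to chromatographic
overlap, charge-state misassignment, or gel densitometry artifacts.

## Problem sizes

The pool-recovery benchmark uses 200 simulated replicates at σ = 0.01 per
truth value; the spectra round trip uses 10 fractions × 20 proteins; the
class-average benchmark uses 120–150 images.  These sizes give stable
statistics (the recovered-pool mean varies by < 0.002 across seeds) while
keeping the full suite under a minute.
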