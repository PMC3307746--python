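# Methods

`repquant` implements two desk-scale analysis pipelines for gnotobiotic
piglet mucosal-immunology studies — TCR Vβ CDR3 spectratype repertoire
inference and negative-control-calibrated immunofluorescence quantification —
together with a synthetic-data generator that supplies inputs with known
ground truth so every stage is verifiable without instrument data.

## Spectratype processing

A spectratype is the distribution of PCR fragment lengths within one TRBV
primer group for one sample; in-frame CDR3 rearrangements produce a ladder
with 3-bp spacing. Peak tables (fragment size in bp, height in relative
fluorescence units) pass two validation rules before any inference:

* **Background rule.** Peaks with height < 70 rfu are not differentiable
  from background fluorescence and are rejected. The inequality is strict:
  a peak of exactly 70 rfu is accepted.
* **Size rule.** Peaks more than 1 bp from the nearest expected in-frame
  fragment size, or outside the group's anticipated size range, are rejected.

The expected-size grid for group *g* is `anchor_g + 3k bp` for integer *k*
spanning the group's range. Anchors and ranges are assay calibration values:
real analyses must supply them (YAML registry); the bundled registry is
synthetic and exists so that the QC rules are exercisable in simulation and
tests. Accepted peaks map to the nearest grid size (an exactly equidistant
peak takes the lower bin index, for determinism); co-binned heights are
summed; binning conserves total accepted height. Heights are then
standardised to proportions of the spectratype total, so a proportion of 1
in a single bin is a maximally restricted repertoire. Spectratypes whose
peaks are all rejected are logged and dropped — the downstream matrix
zero-fills them; there is no imputation.

The repertoire matrix has one row per sample and one column per
(group, CDR3-bin) pair observed anywhere in the cohort, zero-filled, so each
row's slice over one group sums to 1 (or 0 for a failed spectratype). The
matrix round-trips through delimited text bit-exactly (`%.17g` on write,
`float_precision="round_trip"` on read).

## Repertoire inference

* **Ward clustering.** Agglomeration under Ward's minimum-variance criterion
  on squared Euclidean distances over all (group, bin) columns at once,
  unweighted. Merge heights are reported as the increase in within-cluster
  error sum of squares, `(n_a n_b)/(n_a+n_b) ||c_a − c_b||²` — i.e. in
  squared-Euclidean units, matching classic SPSS agglomeration schedules
  (scipy's equivalent heights are `sqrt(2·ΔESS)`). The greedy step is O(n³)
  with a lexicographic tie-break on cluster creation order; repertoire
  cohorts are tens of samples, so the cubic cost is irrelevant and the
  determinism is worth having. Exports: scipy-layout merge table, flat cuts,
  Newick text.
* **PCA.** Exact eigendecomposition of the correlation matrix of the
  z-scored columns, unrotated. Correlation (not covariance) because
  eigenvalue-greater-than-1 (Kaiser) retention is only meaningful when each
  variable contributes unit variance. Iterative-extraction caps found in
  SPSS workflows are an extraction artefact; a closed-form decomposition is
  exact, and the historical cap is recorded as configuration metadata only.
  Zero-variance columns cannot be correlated and are dropped with a warning.
  Eigenvector signs are fixed (largest-magnitude loading positive) so runs
  are reproducible.
* **Factorial GLM.** Per retained component (first 5 by default), a fully
  factorial fixed-effects ANOVA of the score on colonisation status
  (2 levels) and tissue (3 levels) with their interaction, Type-III sums of
  squares under sum-to-zero contrasts (the appropriate choice for the
  unbalanced group sizes typical of gnotobiotic cohorts), via statsmodels
  OLS. Family-wise control is Bonferroni: per-test alpha =
  family alpha / number of components, so 0.05 over 5 components gives
  0.01. Fisher's LSD pairwise comparisons are available for inspection but
  never drive the headline significance calls.

## Immunofluorescence quantification

Each field carries registered greyscale channels (MHCII, SIRPα, CD11R1,
CD16, ...) and a matched negative-control field processed alongside the
sample. Channels are assumed pre-registered (single-colour filters on one
acquisition); there is no registration step.

* **Thresholds.** Per channel, the background threshold is a percentile of
  the negative-control intensities; the default is the 100th percentile
  (the maximum — the strictest reading of "background level"; no
  negative-control pixel exceeds it). A lower percentile (e.g. 99.5) is
  available for robustness to hot pixels.
* **Binarisation.** A pixel is positive iff strictly above threshold.
* **Outcome.** Proportion of positive pixels over the whole image — no
  region-of-interest masking; crypt vs villus framing is an acquisition
  choice, not a computed segmentation.
* **Subsets.** MHCII+ pixels are partitioned into the 8 Boolean combinations
  of SIRPα/CD11R1/CD16. The partition is exact by construction: counts sum
  to the MHCII+ count and SIRPα+ / SIRPα− shares sum to 1. The
  triple-negative combination is constitutive endothelial MHCII and is
  reported separately from the myeloid subsets.
* **ANOVA.** Proportion-positive outcomes are tested on treatment
  (colonisation status) and age. The default unit of analysis is the
  per-animal mean of its fields, because the experimental *n* is animals;
  per-field rows are retained for diagnostics. A field-level mode with the
  animal as an additive categorical block exists but is diagnostic only:
  with animals nested in treatment groups, a field-level treatment test is
  pseudo-replication. (A numeric "animal as covariate" option exists and is
  off by default; a categorical identity has no meaningful slope.) Type-III
  sums of squares; the interaction is dropped with a warning when a design
  cell is empty; Bonferroni per-test alpha = family alpha / number of
  subset outcomes tested.

## Synthetic data

The generator's defaults define the simulated study conditions and are not
adjusted per analysis.

**Spectratypes.** For each tissue and group a base profile over 9 CDR3 bins
is fixed per cohort: spleen uses a discretised Gaussian (σ = 1.5 bins);
jejunal tissues temper that Gaussian with a sparse Dirichlet draw
(sparsity 0.4, exponent 0.3), giving a skewed profile with tissue-specific
dominant bins — the signature of tissue-restricted clone recruitment, and
the reason samples cluster by tissue rather than by animal or status. Each
sample × group profile is then Dirichlet-distributed around the tissue base
with concentration 60 (spleen: tight, Gaussian-like, diverse) or 3
(jejunum: noisy, oligoclonal). Probabilities scale to a 5000-rfu
spectratype; peaks sit on the 3-bp grid with Gaussian size jitter
(sd 0.15 bp, clipped at ±0.9 bp so every true peak survives the 1-bp QC
rule and ground truth stays exact); Poisson(3) noise peaks per spectratype
are drawn uniformly over the size range with heights in U(10, 69) rfu —
below the 70-rfu rule by construction, so default QC removes all of them.
Signal bins that fall below 70 rfu are legitimately rejected at QC; the
stored ground truth includes per-bin rfu, so the expected pipeline output
(surviving bins renormalised) is computable exactly. An optional
colonisation effect (shared "public clone" expansion, mixing weight 0.35,
off by default because the emulated design found none) makes the GLM's
power testable, not just its type-I error.

**Image fields.** Non-overlapping ellipses (radius 4–8 px) are placed by
rejection sampling (a capacity check rejects configurations that cannot
fit; overlap handling is out of scope, keeping ground-truth fractions
exact). Every cell is MHCII+ and positive exactly in its subset's channels;
signal is N(30000, 2000) and background N(1200, 150) on a 16-bit scale,
with negative controls drawn from the same background distribution — so a
maximum-of-negative-control threshold yields a false-positive area of order
1/(number of pixels), and subset recovery is accurate to ≈1e-4 in absolute
area against the ±0.02 tolerance used in tests.

**Area tables.** For ANOVA calibration the per-animal subset areas are
drawn directly from the between-animal model — Normal(group mean,
CV × group mean) truncated at 0, between-animal CV 20%, within-animal field
noise CV 5% over 10 fields — which is orders of magnitude faster than
rendering and measures exactly the inference layer.

**What the simulations do not emulate:** PCR amplification bias, true
sequence-level clonal structure, instrument base-calling, optical blur/PSF,
cell overlap and morphology, illumination gradients, and operator framing
of crypt vs villus regions. Passing tests therefore validate the
*computational* pipeline — QC arithmetic, partition exactness, estimator
calibration — not the biology of any particular cohort.

## Problem sizes and verification

The test-suite and the acceptance script size their Monte-Carlo studies for
a single desktop CPU: 200 replicate cohorts (8 animals × 3 tissues ×
21 groups) for the tissue-not-status pattern; 500 replicates for null ANOVA
calibration; 200 for selective-effect power; 1000 random peak lists and 200
random instances (n ≤ 8) for the brute-force QC and Ward oracles. With
tissue-specific clonality and no status effect, the pipeline flags a tissue
effect at the corrected alpha in ~100% of replicates, a status effect in
~5% (the family-wise chance level), and cuts the dendrogram into
tissue-pure clusters (mean adjusted Rand index vs tissue 1.0; vs status
≈ 0).

One documented failure of an intended property: with 3 animals per group
analysed at the animal level, a doubling of one subset's mean area under
20% between-animal CV is detected at the Bonferroni-corrected alpha
(0.05/8) in only ~35% of replicates — the contrast has 4 error degrees of
freedom, so its analytic power at that alpha is far below the ≥80% one
might expect from a normal approximation. The corresponding test states the
intended ≥80% bound and fails honestly; reaching that power at n = 3 would
require treating fields as independent units, which the package
deliberately refuses to do by default.

## Known limitations

* Per-group anchor/range calibration for real capillary data is not
  bundled and must be supplied.
* The threshold statistic of historical ImageJ macro workflows is not
  published; the maximum-of-negative-control default is an explicit,
  configurable choice.
* The Boolean subset partition is pixel-wise; it does not attempt cell
  segmentation, so colocalisation is interpreted at area, not cell, level.
* Ward clustering is O(n³) and intended for cohort-scale (tens to a few
  hundred samples) matrices.
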