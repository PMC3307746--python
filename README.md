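# repquant

Desk-scale re-implementation of two quantitative pipelines used in
gnotobiotic (germ-free vs defined-microbiota) piglet mucosal-immunology
studies:

1. **TCR Vβ CDR3 spectratype analysis** — quality control of capillary-
   electrophoresis peak tables, standardisation to CDR3-length proportion
   profiles across 21 porcine TRBV groups/subgroup, and repertoire-diversity
   inference by Ward hierarchical clustering (squared Euclidean), unrotated
   correlation-matrix PCA with Kaiser retention, and a fully factorial GLM of
   component scores on colonisation status × tissue with Bonferroni control.
2. **Multi-channel immunofluorescence quantification** — per-channel
   background thresholds taken from matched negative-control fields,
   strict above-threshold binarisation, proportion-positive area over the
   whole image, Boolean partitioning of MHCII⁺ (antigen-presenting-cell)
   pixels into the 8 SIRPα/CD11R1/CD16 subsets, and treatment × age ANOVA
   with the animal as the unit of analysis.

A synthetic-data module generates both input types with known ground truth
(Dirichlet CDR3-bin profiles with tissue-specific clonality; rendered
ellipse "cells" with known subset identities), so the full pipelines are
testable end to end without instrument data. It is aimed at immunologists
analysing spectratype or quantitative-immunohistology readouts, and at
anyone needing a reproducible reference implementation of these classic
workflows.

## The statistics in brief

For each sample × TRBV group, peaks below 70 rfu (background) or more than
1 bp from the nearest expected in-frame size are rejected; surviving peaks
are binned on the 3-bp CDR3 ladder and standardised,
*p̂ₖ = hₖ / Σⱼ hⱼ*, so a single-length (fully restricted) spectratype has
*p̂ = 1*. The samples × (group, bin) matrix is clustered with Ward's
criterion, Δ*ESS* = *n_a n_b*/(*n_a*+*n_b*) ‖c̄_a − c̄_b‖², and decomposed by
PCA of the correlation matrix, retaining components with eigenvalue > 1;
each retained score is tested with a two-way fixed-effects ANOVA
(Type-III SS) on status and tissue at per-test α = 0.05/5 = 0.01.

For images, pixel *x* is positive in a channel iff *x* > the percentile
(default: maximum) of that channel's negative control; the 8 Boolean
subsets partition MHCII⁺ pixels exactly, and the triple-negative subset is
endothelial MHCII, reported separately.

## Worked example

Simulate a cohort (4 germ-free + 4 colonised animals × spleen, proximal and
distal jejunum, 21 TRBV groups) and run the full spectratype pipeline:

```sh
$ repquant simulate-spectra --seed 3 --out-dir demo/data
[repquant] wrote 6021 peaks for 24 samples to demo/data
$ repquant spectra --peaks demo/data/peaks.csv \
    --registry demo/data/registry.yaml \
    --metadata demo/data/metadata.csv --out-dir demo/out
[repquant] matrix: 24 samples x 188 bins
[repquant] PCA: 22 components retained (eigenvalue > 1.0)
[repquant] GLM: per-test alpha 0.01 over 5 components
```

`demo/out/glm.csv` then contains, for the first two components:

```
component  status_p  tissue_p   interaction_p  tissue_significant
PC1        0.912     5.3e-18    0.664          True
PC2        0.115     1.2e-18    0.144          True
```

Tissue separates the repertoires decisively while colonisation status does
not — the expected outcome, since the generator gives each tissue its own
CDR3 profile shape (Gaussian-like spleen, skewed jejunum) and, by default,
no colonisation effect. `demo/out/clusters_k3.csv` shows the dendrogram cut
at k = 3 recovering the three tissues exactly, with germ-free and colonised
animals mixed inside every cluster. The image pipeline runs the same way
(`repquant simulate-images`, `repquant images`), and `repquant all --seed N
--out-dir DIR` chains everything.

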