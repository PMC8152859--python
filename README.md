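# bodyrsa

Representational similarity analysis of body-part coding in
occipitotemporal cortex, packaged as a tested, reusable pipeline.

Viewing images of isolated body parts evokes distinct multivoxel
activation patterns in the lateral occipitotemporal cortex (LOTC). A
long-standing finding is that these patterns are organized by functional
category: the action effectors (hand, foot, arm, leg) cluster together,
the trunk noneffectors (chest, waist) form a second cluster, and the
face parts (upper face, lower face) a third. `bodyrsa` implements the
full analysis chain used to test that organization in a two-group
(adult vs. child/adolescent) block-design fMRI study — from first-level
GLM through rank-based permutation inference — together with a forward
simulator that plants a controllable three-cluster geometry, so every
stage is testable end to end without access to raw scanner data.

## What it computes

- **Block design / GLM** — 10-condition runs (whole body, chair, 8 body
  parts; 12-s blocks, TR 3 s, 106 volumes of which the first 5 are
  discarded), boxcar regressors convolved with the canonical
  double-gamma HRF, discrete-cosine high-pass filter (1/128 Hz), six
  motion regressors, proportional global scaling to 100, pooled-AR(1)
  whitening, linear contrasts, and sphere-ROI activation detection at
  *P* < 0.01 uncorrected.
- **Split-half RDM** — per participant, the 8×8 dissimilarity matrix
  `D_ij = 1 − r(odd-run pattern_i, even-run pattern_j)`, symmetrized.
- **ANOSIM** — on the 28 ranked pairwise dissimilarities,
  `R = (mean between-category rank − mean within-category rank) / (M/2)`,
  `M = 28`, tested against the **complete enumeration of all
  ₈C₄ × ₄C₂ = 420** assignments of the 8 conditions to classes of sizes
  (4, 2, 2): `P = (1 + #{alternatives with strictly greater R}) / 420`,
  so the minimum attainable *P* is 1/420 ≈ 0.002.
- **Mantel test** — Pearson correlation between two RDMs over the 28
  pairs, null built by relabeling conditions (random draws or exact
  8! enumeration).
- **Decoding** — three-class linear SVM (cost 1, one-vs-one) on run-wise
  betas with leave-one-run-out cross-validation, 100-fold balanced
  subsampling for the unbalanced (4, 2, 2) classes, accuracy reported
  against chance = 1/3, with the same 420-combination permutation test.
- **Group & trait statistics** — 2×2 χ² with Cramér's *V*, Student/Welch
  *t* with Cohen's *d*, mixed-design two-way ANOVA with partial η² and a
  between-subject covariate (ANCOVA), Bonferroni-corrected Spearman
  correlations, partial correlation, and framewise displacement
  (|Δ translations| + 50 mm × |Δ rotations|).

## Worked example

Simulate the default cohort (26 adults, 22 children/adolescents, 80
voxels, planted cohesion κ ≈ 0.75 / 0.65) and run every stage:

```sh
bodyrsa run-all --seed 7 --out demo --n-voxels 80 \
    --n-permutations 999 --n-bootstraps 20
```

prints (abridged):

```
ANOSIM [adult, n=26]: R = 1.000, P = 0.002 (rank 1/420)
ANOSIM [child_adolescent, n=22]: R = 1.000, P = 0.002 (rank 1/420)
Mantel between group-mean RDMs: R = 0.993, P = 0.001
Mean FD group difference: t(25.3) = -119.424, P = 0.000, d = -36.99
Corr-type ANOVA group: F(1,46) = 25.534, P = 0.000, partial eta2 = 0.357
Decoding group_difference: t(46.0) = 2.386, P = 0.02122
Trait Spearman (Bonferroni threshold 0.005): none significant
```

Reading the output: each group's mean RDM separates the three planted
categories completely, so the hypothesized model outranks all 419
alternatives and *P* hits its floor of 1/420 = 0.002. The two group
geometries are nearly identical (Mantel *R* = 0.993). The simulated
child group moves about twice as much (the FD *t*; the sign is
adult − child), and its noisier data lower its decoding accuracy
(group-difference *t*). Group-mean averaging makes the group-level
ANOSIM much cleaner than any single participant's — per-participant
*R* and *P* values are in `demo/participants.csv`.

The same statistics are available as library calls
(`bodyrsa.split_half_rdm`, `bodyrsa.anosim_permutation_test`,
`bodyrsa.mantel_test`, `bodyrsa.decode`, `bodyrsa.mixed_anova`, ...)
on your own arrays, and `bodyrsa anosim --rdm my_rdm.csv` scores any
8-condition RDM saved as CSV.

## Layout

- `bodyrsa.design` — block-design timing and schedules
- `bodyrsa.synth` — forward simulator (patterns, BOLD, motion, cohorts)
- `bodyrsa.glm` — design matrices, GLM, contrasts, ROIs
- `bodyrsa.rsa` — RDMs, MDS, within/between-group correlations
- `bodyrsa.partitions` — ANOSIM, the 420-partition test, Mantel
- `bodyrsa.classify` — SVM decoding with balanced subsampling
- `bodyrsa.groupstats` — χ², t, mixed ANOVA, Spearman, FD
- `bodyrsa.pipeline` / `bodyrsa.cli` — orchestration and CLI
- `docs/methods.md` — models, parameter choices, and limitations
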