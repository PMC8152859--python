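# Methods

## The experimental design being modeled

Each run presents 10 picture conditions (whole body, chair, hand, foot,
arm, leg, chest, waist, upper face, lower face) in 12-s blocks, two
blocks per condition per run, in pseudo-random order. Fixation
baselines of 27 s (before block 1), 12 s (after blocks 5, 10, 15) and
15 s (after block 20) bring each run to 318 s = 106 volumes at TR 3 s;
four runs are acquired and the first five volumes of each are
discarded, leaving 404 analyzed volumes. Block order is drawn as an
independent uniform permutation per run (seed-controlled); no
counterbalancing constraints are imposed, since none are specified for
the task beyond pseudo-randomization. Within-block picture-level events
(12 pictures × 1 s SOA) are carried in the design metadata but the
hemodynamic model operates on block-level boxcars, matching how such
block designs are conventionally analyzed.

## Forward model

Planted condition amplitudes ("patterns") for the 8 body parts follow

    pattern(c) = sqrt(kappa) * prototype(category(c)) + sqrt(1 - kappa) * unique(c)

with prototypes and uniques i.i.d. N(0, 1) per voxel. The cohesion
parameter kappa in [0, 1] is exactly the expected correlation between
two same-category patterns: kappa = 0 gives independent patterns,
kappa = 1 identical ones. Whole-body and chair patterns are independent
N(0, 1) with the whole-body mean raised by `contrast_gain` (default 1),
giving the localizer contrast a planted effect.

A simulated run is `Y = 100 + X B + drift + noise`, where `X` is the
same boxcar ⊗ HRF design the GLM later inverts (so the noiseless
round-trip is exact by construction and is tested to < 1e-8), the
drift is a half-cycle cosine with per-voxel random phase, and the noise
is AR(1) Gaussian parameterized by its stationary SD. Head motion is a
six-parameter random walk; framewise displacement uses the standard
50-mm rotation radius.

Default cohort parameters (26 adults, 22 children/adolescents) and the
reasoning behind them:

| parameter | adult | child | why |
|---|---|---|---|
| kappa mean (SD) | 0.75 (0.10) | 0.65 (0.12) | strong three-cluster geometry in both groups, slightly weaker in the younger group |
| noise SD | 1.2 | 1.8 | sets the run-level beta SE (≈ 0.45 per unit noise for this design) to roughly half the unit pattern SD in adults, lower in children — above chance but off ceiling at the single-participant level |
| motion step (mm / rad) | 0.025 / 0.0003 | 0.05 / 0.0006 | mean FD ≈ 0.10 mm vs ≈ 0.19 mm, the two groups' observed motion levels |
| AR(1), drift | 0.3, 0.5 | same | typical serial correlation and slow drift magnitudes |

Trait scores (SRS, AQ, four SP subscales, DCDQ, MABC-2, age, FSIQ) are
linear in kappa plus N(0, 5) noise, with signs chosen so higher
autistic-trait/sensory scores accompany weaker category organization
and better motor scores accompany stronger organization; age and FSIQ
are uncoupled. This minimal model exists to make Spearman-recovery
testable, not to claim realism of any score distribution.

### What the generator does not emulate

Voxels are independent given the planted pattern; real BOLD has strong
spatial correlation, voxel-wise SNR heterogeneity, and non-Gaussian
artifacts. Consequently multivariate statistics are *easier* here than
on real data at matched amplitude — group-level ANOSIM and linear SVM
decoding typically saturate (R = 1, accuracy 1) at the default
settings, whereas real group RDMs overlap partially. Motion influences
FD but is not coupled into the BOLD signal, so the motion-ANCOVA
machinery is exercised on an honest null rather than a planted
confound. Passing tests therefore certify the *statistical machinery*
(calibration, invariances, worked examples), not biological realism.

## First-level GLM

The canonical HRF is the conventional double-gamma (response delay 6 s,
undershoot delay 16 s, unit dispersions, response:undershoot ratio 6,
32-s support). For regression the kernel is normalized to unit area so
a sustained block converges to plateau 1 and betas are amplitudes in
data units. Design matrices hold the 10 condition regressors (boxcars
convolved on a 30× oversampled grid and sampled at volume times),
mean-centered motion parameters (all-zero columns dropped), a
discrete-cosine high-pass basis with K = floor(2·N·TR/128) components,
and an intercept; rank deficiency is rejected with the offending
columns named. Dummy-volume removal happens before design
construction: onsets shift earlier by 15 s and motion rows are dropped
to match.

Whitening estimates a single AR(1) coefficient from the lag-1
autocorrelation of first-pass OLS residuals pooled over all voxels.
Because OLS residuals of even white noise are negatively autocorrelated
through the hat matrix (about −0.15 for this design), the estimate is
bias-corrected by adding `tr(A H)/(n − p)` (A the symmetrized lag-1
shift) before the whitening filter `y_t − ρ y_{t−1}` (first row scaled
by sqrt(1 − ρ²)) is applied to data and design. With this correction
white noise yields ρ ≈ 0 and a planted ρ = 0.4 is recovered within
sampling error.

Global scaling multiplies each run so its grand mean is 100 (the
standard proportional-scaling constant). Contrasts pool over runs as
fixed effects (mean effect, summed dof); activation within a sphere ROI
(8-mm radius on a 2-mm grid → 257 voxels, boundary inclusive) is any
voxel above the one-sided t quantile at P = 0.01 with the pooled dof,
and activation size is the suprathreshold count times voxel volume — no
cluster-level machinery.

## RSA and inference

Split halves are runs {1, 3} vs {2, 4} by acquisition order (the
simplest stable convention). The directed matrix
`D_ij = 1 − r(odd_i, even_j)` is symmetrized as `(D + Dᵀ)/2`; the
diagonal (1 − split-half reliability) is retained in the matrix but
excluded from every vectorized statistic — ANOSIM, Mantel and the
within/between-group correlations all operate on the 28 unordered
pairs. MDS is metric least-squares stress (SMACOF) with seeded
restarts, reporting Kruskal stress-1; nonmetric MDS is not the default.
Within/between-group correlations are Pearson on the 28-pair vectors,
with the own-group mean computed leave-one-out; they feed a correlation
type × group mixed ANOVA.

ANOSIM ranks the 28 dissimilarities with average ranks for ties;
`R = (r̄_between − r̄_within)/(M/2)`. The null enumerates all 420
labeled (4, 2, 2) partitions in deterministic lexicographic order.
Because the two size-2 classes are interchangeable, every unlabeled
grouping appears exactly twice (210 distinct), so the observed model's
own duplicate always ties it; counting only *strictly greater*
alternatives keeps the minimum attainable P at 1/420 ≈ 0.002 (printed
as 0.002), which is also why the enumeration's R values average to
exactly zero. The Mantel null permutes condition labels of one matrix
(simultaneous row/column permutation), default 9999 draws with an
exact 8!-relabeling option; P = (1 + #{null ≥ observed})/(n + 1).

## Decoding

One sample per condition per run (the run-wise beta pattern), linear
SVM with cost 1 and one-vs-one voting, leave-one-run-out folds.
Features are standardized with training-fold statistics only
(zero-variance features dropped with a warning); each of the 100
balanced bootstraps subsamples every class down to the minority count
(2 per run under the hypothesized partition) without replacement,
trains one classifier, and is scored on the full held-out run;
accuracies average over bootstraps then folds, reported against chance
1/3. The 420-combination permutation test reuses the ANOSIM
enumeration and strict-counting convention.

## Group statistics

The 2×2 χ² is the uncorrected Pearson statistic (this is what
reproduces the worked examples 6.596 and 1.207 exactly; Yates
correction is available by flag) with Cramér's V = sqrt(χ²/N). The
two-sample t offers Student and Welch explicitly rather than gating on
a variance test; Cohen's d always uses the pooled SD. The mixed ANOVA
uses the classical sums-of-squares decomposition — between-group effect
against subjects-within-groups, within effect and interaction against
the subject × within stratum — with partial η² = SS_eff/(SS_eff +
SS_err). An optional participant-level covariate (e.g. mean FD) is
grand-mean centered and entered in the between-subject stratum only,
costing one error df there; within-stratum tests are unchanged by
design. Spearman correlations report both uncorrected and
Bonferroni-corrected (0.05/m, = 0.005 for the 10 trait scores)
significance; partial correlation residualizes both variables on the
covariate and tests with df = n − 3.

## Numerical and problem-size choices

Pipelines and tests run on deliberately small instances — 40–120
voxels, cohorts of 2–48, 10–100 bootstraps, hundreds of null seeds —
chosen so the full suite certifies calibration properties (type-I error
of activation detection at 1%, uniform null P for ANOSIM/Mantel,
unbiased decoder at chance) with Monte-Carlo error well inside the
asserted tolerances. All randomness flows through
`numpy.random.default_rng` seeds recorded in each run's provenance
block; re-running a pipeline with the same config reproduces its CSV
outputs byte-identically. Strict-greater comparisons in permutation
tests use a 1e-12 tolerance to make ties robust to floating-point
noise.

## Known limitations

- The 420-model enumeration is exact only for the (4, 2, 2) design;
  other size multisets are supported by the same code but have
  different null supports.
- Real-data NIfTI support covers loading runs/masks and writing voxel
  maps; spatial preprocessing (realignment, normalization, smoothing)
  is out of scope and must be done upstream.
- The mixed ANOVA requires a complete within-factor design; missing
  cells are rejected rather than imputed.
- Welch t-values computed from rounded summary statistics can differ
  from values computed on raw data at the second decimal; only the
  Satterthwaite df is stable under that rounding.
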