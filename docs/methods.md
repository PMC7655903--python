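# Methods

This note records the statistical models implemented in `popgs`, the
defaults and the reasoning behind the choices that were genuinely open.

## Population and trait simulation

`synthetic_data` generates a single-cohort breeding population:

* **Mating design.** `study_population_design()` embeds the corrected cross
  table of the reference population — 12 sires x 11 dams, 35 full-sib
  families, 1,011 offspring, family sizes 10–118, containing a partial 4x4
  factorial block plus pair and multi-pair matings.  Any other design can be
  declared through `MatingDesign`.
* **Genomes.** Founders are drawn in Hardy–Weinberg and linkage equilibrium
  with allele frequencies uniform on a configurable MAF range (default
  0.05–0.5) over `n_chromosomes` chromosomes (default 19, matching the
  poplar karyotype; 50 Mb each).  The simulation's true frequencies are
  recorded in the marker map (`true_freq`) so that expectation checks can
  centre genomic matrices on the actual base population.  Offspring receive
  one recombined gamete per parent; crossovers are Poisson with rate
  `recomb_rate_per_mb x chromosome length` (default 0.01/Mb = 1 cM/Mb) and
  no interference.  Mendelian consistency is exact by construction.
* **Traits.** A finite-QTL model: one QTL panel (default 100 QTL) shared
  across traits, per-QTL additive effects multivariate normal over traits
  with the declared genetic correlation matrix (pleiotropy creates the
  trait correlations), optional dominance deviations scaled to a declared
  ratio of the additive variance.  Realised TBVs are centred and rescaled
  so the additive SD equals `additive_effect_scale` exactly, which makes
  the downstream heritability calibration deterministic.  The QTL count is
  a convention, not an estimate: real trait architectures of the study
  species are unknown, and `n_qtl` spans oligogenic (10) to
  quasi-infinitesimal (`n_markers`) regimes for the weighting experiments.
* **Field trials.** Each block is a horizontal band of the layout holding
  one ramet of every genotype at a randomised plot (a randomised complete
  block design, default 6 blocks).  An observation is
  `trait mean + genotypic value + surface + iid residual`.  The residual
  variance is calibrated so the broad-sense heritability of clonal means
  equals `target_h2` (defaults average 0.73, the moderate-to-high range
  typical of well-replicated clonal trials); the surface is a low-rank
  tensor B-spline draw (matching the fitting model; a Gaussian-process
  option exists for misspecification experiments) scaled to
  `spatial_variance_fraction` (default 0.15) of the plot-level variance,
  with correlation length `spatial_range` (default 10 plots).
* **Pedigree errors.** `corrupt_pedigree` replaces the sire of whole or
  partial full-sib family blocks (contiguous runs within randomly ordered
  families) until the requested offspring fraction (default experiments use
  0.15) is reached — mimicking mislabelled complete or partial crosses,
  the dominant error mode in controlled crossing programs.

What the generator does **not** emulate: genotype imputation errors (the QC
table filters are exercised on synthetic QC values), multiple trials with
batch effects, genotype-by-environment interaction, selection over
generations, selfing, or sequence-level variation.  Tests passing on this
generator therefore demonstrate the correctness and calibration of the
estimators under the assumed model, not robustness to those departures.

## Relationship matrices

* **A** by the tabular method, founders unrelated and non-inbred.
* **Pedigree dominance**: `D(X,Y) = 0.25 (A(a,c)A(b,d) + A(a,d)A(b,c))`
  with unit diagonal (non-inbred convention; entries involving unknown
  parents are zero).
* **Genomic G**: VanRaden cross-product of centred dosages with trace
  normalisation, `trace(G)/n = 1` exactly; optional diagonal marker
  weights (rescaled to mean 1).  Centring frequencies default to the
  observed frequencies of the genotyped set — the standard self-contained
  choice — with an `allele_freq` argument for declared base-population
  frequencies.  With few founders the trace scaling shifts entry means by
  a few percent relative to pedigree expectations; this is a property of
  the estimator, and the expectation tests therefore centre on the true
  simulated frequencies.  The trace-normalisation constant is stored on
  the matrix so marker effects can be back-solved on the same scale.
* **Genomic dominance**: heterozygosity indicator centred by `2 p q`,
  normalised identically.
* **Pedigree correction** uses opposing-homozygote exclusion with a
  threshold expressed as a fraction of compared markers (default 0.01,
  tolerating ~1% genotyping error).  A flagged parent is replaced by the
  declared candidate of the same role with the smallest count (below
  threshold), else set unknown.  Candidates include genotyped founders
  that currently appear in no parental role, so a parent whose every
  offspring was mislabelled can be recovered.  The procedure is idempotent.
* **Effective size** is the status number `1/(2 f̄)` with `f̄` the mean
  coancestry (including self-pairs) of the group, defaulting to the
  parental set — the parents define the breeding population's diversity.

Marker panels: QC filters are strict inequalities (Props > 0.90,
cProps > 0.60, MAF > 0.05 by default).  Window thinning uses 1-based
half-open windows anchored at position 1; within a window the highest
Props wins, ties by highest cProps, then lowest position.

## REML and BLUP

All variance components are estimated by EM-REML.  The EM update for a
variance component with structure `K` is
`s' = s + s^2 (y'P K P y − tr(P K))/q` (`q` = rank of the folded
structure), and the residual analogue with `K = I`; each step provably
never decreases the restricted likelihood.  Acceleration combines three
candidate moves per iteration — the plain EM update, an
average-information (AI) Newton step where the model class provides one,
and a squared (Aitken delta-squared / SQUAREM) extrapolation through two
EM updates, plus a snap-to-boundary candidate for components decaying
harmonically toward zero — accepting whichever attains the highest
restricted likelihood, so the trace stays monotone by construction.
Validation against direct numerical optimisation of the restricted
likelihood agrees to ~1e-8 on all paths.

Three computational paths share this driver:

1. **Single kernel** (A-BLUP, G-BLUP): the model is folded to the
   phenotyped subset (identical marginal likelihood) and rotated by the
   eigenbasis of `K_ff`, making each step O(n).
2. **Several kernels** (additive + dominance): dense n x n covariance per
   step.
3. **Replicated observations** (spatial adjustment): Henderson's MME with
   EM trace terms from the inverse coefficient matrix.

BLUPs for every individual in `K` — phenotyped or not — come from
`u = s K[:, f] P y`; an individual unrelated to all phenotyped ones gets
exactly 0.  Convergence requires relative log-likelihood change < 1e-8
**and** relative change of every component < 1e-6 within 500 iterations
(errors carry the last iterate).  Variances are floored at 1e-8 times the
phenotypic variance; components pinned there are flagged.  Fixed effects
default to an intercept because responses are pre-adjusted clonal means.
AIC counts only the estimated (co)variance parameters; since every model
here has the same single fixed effect, including it would shift all AICs
equally.

**Multi-trait** models estimate unstructured genetic and residual
covariance matrices.  With complete data the same eigen-rotation makes
rows independent t-variate normals (matrix-variate EM); with per-trait
missing values the EM runs on the observed entries, each individual
contributing the traits it has, with missing cells handled as additional
latent data (exact EM, monotone).  Non-PD updates are bent to the nearest
PSD matrix and flagged; a genetic correlation within 0.001 of ±1 raises a
boundary warning.

## Spatial adjustment

Per trait: `y = mu + genotype + surface + residual`, genotype correlated
by the pedigree A matrix, surface coefficients i.i.d. with one common
variance, on a tensor-product basis of clamped cubic B-splines with `k`
equally spaced knots per axis (`(k+2)^2` coefficients; rows are a
partition of unity).  Surfaces are built per trial (block-diagonal design)
and centred within trial after fitting, the mean moving into the
intercept.  The genetic term uses A alone — the single-matrix
simplification of the original blended-relationship adjustment.  Knot
pairs (default grid {4, 6, 8, 10} squared) are compared by REML-based AIC;
among pairs within delta-AIC = 2 of the minimum (statistically
indistinguishable by the usual convention) the smoothest surface wins,
which keeps null fields from selecting rough surfaces on noise.  Adjusted
clonal means subtract the fitted surface and average over retained blocks;
restricting to blocks {1, 3, 5} yields the degraded-phenotype variant.

## Weighted G-BLUP

Iteration 0 is plain G-BLUP.  Each iteration back-solves marker effects
`u = W X' G^{-1} g_hat` with `X` the same centred coding used to build the
matrix (centred dosages for additive, centred heterozygosity for
dominance — the coding consistency is a package decision where the
notation was ambiguous), squares them into weights, rescales weights to
mean 1 (so the weighted trace normalisation stays comparable across
iterations), rebuilds G (and D when dominance is modelled) and refits.
Three iterations produce Gw1–Gw3; the count is configurable.  Weights are
invariant to phenotype location shifts, and `trace(Gw)/n = 1` holds at
every iteration.  Dominance weights are only formed when the model
includes dominance.

## Evaluation

Cross-validation uses independent resamples (default 10) rather than
disjoint folds — matching how repeated-split accuracy distributions are
usually reported — with a classical disjoint-fold mode behind a flag.
Individual sampling draws the training fraction regardless of family;
family sampling draws whole full-sib families.  TestSet ids are excluded
from every training set, and a programmatic no-leakage assertion guards
every scenario cell.  Per-repetition seeds are `base_seed + repetition`.

Metrics: predictive ability (Pearson r of predictions vs adjusted clonal
means), accuracy (predictive ability / sqrt of the reference-model h2;
values > 1 are legitimate), Spearman and Pearson within observed-value
tiers (default 0–5%, 5–10%, 10–50%, 0–100%, best-first ordering
configurable per trait direction since low scores are better for, e.g.,
disease traits), the bias regression of observed on predicted, and
within-family gain: per family with >= 3 evaluated members,
`r(genomic, obs) − r(pedigree, obs)`, family-size-weighted mean.  A
prediction constant within a family (the pedigree parent average for a
held-out family) has no within-family information and scores 0 by
convention.  Correlations on tied data use average ranks (Spearman).

## Problem sizes used by the test suite and acceptance script

The package's own experiments run at desk scale: the full 1,011-offspring
study design for pedigree bookkeeping and heritability recovery (30
replicate simulations, 300 markers); ~300–500-offspring scaled versions
(family sizes x 0.3–0.5, 1,000–2,000 markers over 10 chromosomes) for the
cross-validation, weighting and spatial experiments; 200 x 1,000 for the
SNP-BLUP equivalence check; and an 80-sire/160-dam shallow design with
5,000 markers for relationship-expectation checks.  These sizes keep every
simulation oracle's standard error well below the tolerance it checks.

## Known limitations

* The dominance matrix diagonal uses the non-inbred convention (1); with
  substantial inbreeding the pedigree dominance matrix is approximate.
* The spatial model shares one spline-coefficient variance across trials
  and uses i.i.d. coefficients; anisotropic or AR1xAR1 alternatives are
  out of scope.
* Single-step blended relationship matrices, Bayesian whole-genome
  regression and G x E models are out of scope.
* Multi-trait fits with many traits and heavy missingness use the dense
  observed-entry EM and scale accordingly (fine for the t <= 7 study
  setting at desk scale).
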