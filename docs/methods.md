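# Methods

`cnvdose` implements a federated analysis of recurrent copy-number-variant
(CNV) dosage effects on adult height and BMI: locus-level CNV genotyping
from raw interval calls, harmonized within-cohort trait scaling, per-cohort
regression, inverse-variance meta-analysis, and the downstream analyses that
characterize dose-response structure, sex differences, developmental
trajectories, mediation, and subregion additivity. This note documents the
models, the choices made where the design was open, and what the synthetic
validation data do and do not establish.

## CNV genotype assignment

Recurrent CNVs arise by non-allelic homologous recombination between
segmental-duplication clusters, so carriers share approximately the same
breakpoints. A hotspot is an ordered run of breakpoint segments (one segment
for simple loci; A-B … G-H for the 22q11.2-like architecture); a testable
allele is a contiguous span of segments with a DEL or DUP state.

Assignment rule: for each sample and state, same-state calls are merged
(interval union) first — callers fragment large events and fragmentation
should not be penalized. A span is state-positive when the merged calls
cover at least `min_fraction` (default 0.5) of **every** segment in the span
and of **no** flanking segment. Exactly one positive state yields that call;
neither yields REF; both yield NO_CALL (logged — the data are contradictory
and a conservative missing value avoids fabricating a genotype).

Two overlap semantics exist in the field: fraction of the *target* region
(the stated intent of a 50%-of-target rule) versus fraction of the *call*
(bedtools `-f 0.5`). The default is fraction-of-target; `overlap_mode="call"`
preserves the alternative. Coordinates are 0-based half-open everywhere; the
catalog loader accepts `one_based=True` and converts on read, and the input
validator flags catalogs whose consecutive segments abut with a 1-bp gap
(the signature of 1-based inclusive coordinates).

The default catalog's flanking set for each span is the complement of the
span within its locus, which makes allele categories mutually exclusive
(an A-D carrier is not also counted as an A-B carrier) and reproduces the
canonical A-D rule: at least 50% of A-B, B-C and C-D, and no CNV over
D-E … G-H. Flanking exclusion is evaluated per state, not jointly.

The packaged catalog (`catalog_default_synthetic.json`) is a
synthetic-coordinate stand-in: 41 single-segment hotspots at approximate
literature coordinates plus one fully segmented 22q11.2-like locus with six
testable spans, for 47 spans and 94 DEL/DUP alleles. The genotyper is
validated against a brute-force base-wise coverage oracle on randomized
locus/call configurations (10,000 instances in the acceptance suite).

## Trait scaling

Adult traits are scaled within each cohort so that regression coefficients
are in SD units of the sex- and age-corrected trait and therefore
comparable across cohorts with different demographics:

1. residualize `y ~ sex + age + age²` by least squares;
2. split by sex; shift residuals by `(−min + 1)` to positive support;
3. Box-Cox transform with the maximum-likelihood λ (searched in [−5, 5]);
4. standardize to mean 0, SD 1; recombine sexes.

The per-sex split equalizes variance across sexes (a prerequisite for
interpreting sex-stratified and interaction estimates); the Box-Cox step
normalizes skewed residuals without pulling outliers toward the mean, so
large carrier effects are not deflated. The transform is strictly monotone
within sex, so ranks are preserved exactly.

Known limitation: the unit pedestal "+1" in the positivity shift is not
scale-equivariant, so re-expressing the raw trait in different units (cm vs
m) changes the estimated λ slightly. Ranks are invariant exactly and the
scaled values agree closely (r > 0.999 for near-normal residuals, r > 0.95
for strongly skewed ones), but not to machine precision. A scale-equivariant
pedestal would restore exact invariance at the cost of changing the
transform's behavior near the support boundary; the conventional unit
pedestal is kept.

Pediatric measurements are expressed as age/sex z-scores via the LMS method:
z = ((value/M)^L − 1)/(L·S) with L, M, S linearly interpolated in age within
sex (log limit at L = 0). The packaged LMS table
(`lms_reference_synthetic.tsv`) is a smooth synthetic reference for ages
2-20, not WHO/CDC data; analyses of real cohorts should substitute the
appropriate published reference via `LmsReference.from_tsv`. The age-18
boundary separates adult scaling from pediatric z-scores.

## Per-cohort association models

- Main effects: `scaled trait ~ factor(genotype, ref=REF) + PC1..PC10`.
  NO_CALL samples are dropped for that span only. A coefficient of −0.5 for
  DEL means carriers sit half a cohort-SD below non-carriers of the same sex
  and age.
- Interactions: `scaled trait ~ genotype × moderator + PC1..PC10`, where the
  moderator is a within-cohort standard-normal PGS or sex (0/1). Moderator ×
  PC terms are not included.
- Variance explained: R² of (all spans as factors + PCs) minus R² of (PCs
  only), computed on the same rows (samples with NO_CALL at any span are
  excluded from both fits).
- Medications: per-sample category flags (antidepressant, antipsychotic,
  mood stabilizer; `any` = union) from prescribed-code lists; enrichment in
  carriers by 2×2 chi-square without continuity correction.
- Stratified means: raw-trait means per genotype × PGS-quartile (and/or
  medication) cell. Quartile boundaries use the full cohort by default;
  carriers are rare enough that the distortion is negligible (a
  non-carrier-only option exists).

Adult fits exclude participants under 18. Sex-stratified fits exclude
cohorts where either sex exceeds 75% of the sample (configurable), mirroring
the exclusion of heavily sex-imbalanced cohorts from sex analyses.

## Meta-analysis

Fixed-effects inverse-variance pooling: weights 1/SE², pooled SE =
(Σw)^(−1/2), two-sided normal p. Because traits are scaled within cohort,
every cohort estimates the same SD-unit quantity; heterogeneity (Cochran's
Q, I²) is reported for inspection but never switches the estimator to
random effects. Variance explained is pooled on the Fisher-z scale of
√R² with weights n − 3 (the sampling precision of a Fisher-transformed
correlation — the standard choice where the z-scale SE is otherwise
unspecified), then back-transformed and squared; ΔR² is the difference of
pooled full-model and covariate-only values.

Filters applied before pooling: ≥ 10 combined carriers for main effects
(the "at least 10 subjects" convention, applied inclusively), ≥ 200
combined carriers for interaction tests. Multiple-testing correction is
Bonferroni with m = 47 for main effects and m = 32 for interactions.

## Dose-response decomposition

For spans with ≥ 10 carriers of both alleles, the meta-analysed (beta_DEL,
beta_DUP) pairs form a dose-response scatter; mirror loci fall on a
negative-slope line, buffered/asymmetric loci on a near-zero-slope line. The
decomposition fits a k-component mixture of linear regressions of beta_DUP
on beta_DEL by EM. Each point's known sampling variance SE_DUP² is added to
the component residual variance; component lines are updated by weighted
least squares and residual variances by a 1-d profile search inside each
M-step. Twenty seeded restarts run a short burn-in and the best is polished
to convergence; k is selected by BIC (−2LL + p ln n, p = 3k + k − 1), with
AIC available. k = 1 reduces to iterated weighted least squares.

SE_DEL on the x-axis is ignored by the default fit — a known attenuation
source (regression dilution) that biases slopes toward zero but not
component membership; the model class was chosen as the minimal one that can
express "two linear components".

## Sex differences

Sex-stratified per-cohort fits are pooled per sex; female effects are
regressed on male effects across loci and deviation from the identity line
is tested by a joint F-test of {intercept = 0, slope = 1}. A numerically
perfect fit (zero residual) short-circuits the 0/0 F statistic: p = 1 on the
identity line, p = 0 off it. For loci too small to test individually, per-
locus female-minus-male contrasts (SE = √(SE_F² + SE_M²); stratified fits
use disjoint samples, so the independence is exact) are pooled within groups
defined by the main effect: Bonferroni-significant positive, significant
negative, or neutral.

## Developmental trajectories

Trajectory models use fixed-df natural cubic spline bases rather than
penalized smooths so that nested likelihood-ratio tests have an exact
chi-square null reference; `basis_df` (default 5) counts dimensions beyond
the constant carrier offset. The null model is a constant carrier offset;
the full model gives carriers a spline function of age. Pediatric z-scores
from a correct reference have mean 0 at every age in non-carriers, which the
generator's output passes as a gate before any trajectory test.

The group comparison (obese/lean at a BMI percentile, sex, PGS quartile)
fits one shared smooth versus group-specific smooths (which contain the
group offset), LRT df = basis_df + 1 — the mgcv idiom `s(age)` vs
`group + s(age, by=group)`. The obesity split defaults to the 90th
percentile of the BMI z distribution with a 30th-percentile preset for
alleles where obesity is too sparse to split evenly.

## Mediation

Age-binned cross-sectional mediation on raw phenotype values (upper bin
edges exclusive): mediator model `BMI ~ sex + age + CNV`, outcome model
`height ~ BMI + sex + age + CNV`; ACME = a·b (product of coefficients),
ADE = the outcome-model CNV coefficient; percentile bootstrap (default 1000
resamples, seeded) for CIs. In the all-linear no-interaction specification
ACME + ADE equals the total-effect coefficient to machine precision on
noise-free data. The reverse direction swaps mediator and outcome. Ancestry
PCs are not included in mediation models, matching the stated model
formulas. Bins with < 10 carriers are reported as underpowered; bins whose
fits are singular (e.g. no carriers) are reported with NaN estimates rather
than aborting the run.

A structural note: in jointly Gaussian cross-sectional data, the forward and
reverse indirect-path t statistics are equal (partial correlation is
symmetric), so the directional falsification — forward ACME significant,
reverse ACME null — is informative precisely when the total CNV→height
effect is near zero, i.e. when a negative direct path opposes a positive
mediated path. That is the deletion archetype the generator plants, and the
configuration under which the reverse-null check is meaningful.

## Subregion additivity

For a composite span (A-D) over disjoint components (A-B, B-C, C-D), the
additive expectation is the sum of component betas with SE = √(ΣSE²).
Component and composite carriers are disjoint groups; they share the REF
pool, which induces a small positive covariance that is ignored (carrier
variance dominates at these frequencies, making the test slightly
conservative). The deviation test is z = (observed − expected)/√(SE_obs² +
SE_exp²); a significant deviation (α = 0.05, uncorrected — one pre-specified
composite test per locus) with |observed| < |expected| is tagged
sub-additive (buffering), otherwise super-additive. The expectation operator
is associative by construction. An accompanying profile classifies
component pairs as opposing (cancellation) or reinforcing by sign agreement
among significant components.

## Synthetic data generator

The generator defines the validation conditions; its defaults emulate the
structure of the study the pipeline targets:

- cohorts of differing size, sex ratio and age range; one RNG stream per
  cohort spawned from the master seed, so outputs are bit-reproducible and
  existing cohorts are unchanged when cohorts are appended;
- per-allele carrier assignment by Bernoulli draws, mutually exclusive
  within a locus (NAHR events at frequencies ≤ 5e-3 essentially never
  co-occur in one genome); a `carrier_enrichment` multiplier emulates
  clinically-ascertained pediatric cohorts recruited on carrier status;
- raw calls per carrier with Gaussian breakpoint jitter (default SD 10 kb,
  small relative to segment lengths but enough to exercise the 50%
  threshold), optional fragmentation, and a configurable spurious-call rate;
- standard-normal PGS and PCs; adult latent traits with unit variance
  (noise SD = √(1 − β_PGS²)), so planted carrier effects are directly in
  the SD units the pipeline estimates; raw traits add sex/age means
  (height ≈ N(176, 6.5²) cm for males) to exercise residualization;
- pediatric phenotypes generated on the LMS z scale (non-carrier z ~ N(0,1)
  at every age — the generator's calibration gate) and inverted to raw
  measurements through the packaged reference; BMI is generated before
  height so mediation paths (a: CNV→BMI; b: BMI→height) are well-defined;
- medication flags from a logistic model with baseline rates 12%/3%/4%
  (antidepressant/antipsychotic/mood stabilizer — population-scale lifetime
  prevalences), per-allele carrier odds ratios, and a BMI feed-forward term;
- a demo effect map with the field's headline archetypes: a 16p11.2-like
  mirror pair with a child-short/adult-tall DUP trajectory and an
  obesity-mediated DEL, a segmented 22q11.2-like locus with opposing
  A-B/C-D DUP effects (cancellation) and a sub-additive A-D DEL (0.6× the
  component sum), and a 15q11.2-like female-biased BMI allele.

What the generator does not emulate: linkage disequilibrium and haplotype
structure, platform-specific intensity noise and call-quality models,
relatedness, longitudinal repeated measures, non-Gaussian trait tails
beyond what Box-Cox handles, and real ancestry structure (PCs are exogenous
noise except where confounding is explicitly planted). Passing tests
therefore establish the statistical machinery's correctness and calibration
under the stated generative assumptions, not robustness to every artifact of
real biobank data.

## Problem sizes and numerics

The test and acceptance runs use desk-scale problem sizes chosen to keep the
full suite reproducible on a single CPU: effect recovery uses 5 cohorts of
100k samples over 200 replicates (the planted effect, −0.341 SD at carrier
frequency 5e-4, is the scale at which recurrent-CNV effects sit);
interaction calibration uses 1,000 replicates of n = 4,000 with 200
carriers; the demo pipeline runs 3 adult cohorts (20k/12k/8k) plus one
enriched pediatric cohort (6k). Degenerate inputs are handled explicitly:
empty call sets genotype REF everywhere, zero-carrier bins and strata are
reported rather than imputed, collinear genotype columns in the joint R²
model are dropped with a warning, and EM non-convergence returns the
best-so-far fit flagged `converged=False`. All stochastic components
(generator, EM restarts, bootstrap) are seeded; reruns with one seed are
byte-identical through the entire pipeline.
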