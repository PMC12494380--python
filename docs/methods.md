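# Methods

`txaging` quantifies sex- and age-driven variation in bulk transcriptomes
(gene-level TPM and splice-event PSI), identifies age-by-sex differential
features, reconstructs splicing-factor (SF) regulatory links, and
estimates sex-dimorphic aging rates with breakpoint detection.  All
stages are validated on synthetic cohorts whose structure is planted and
therefore known exactly.

## The synthetic cohort model

Expression is generated on the log-TPM scale and splicing on the
logit-PSI scale as

    link(y)_ij = baseline_i + planted_ij + batch_ij + noise_ij,

then back-transformed, keeping TPM positive and PSI in [0, 1] without
clipping.  Gene baselines are log-normal (mean log TPM 2.0, SD 1.0, so a
typical gene sits near 7 TPM); per-gene noise SDs are uniform on
[0.3, 0.6] log units; event baselines are uniform PSI in [0.15, 0.85]
with logit noise SDs in [0.25, 0.45].  These are stand-ins chosen to
resemble moderately expressed protein-coding genes and quantifiable
splice events; they are exposed in `CohortConfig`.

Planted effect magnitudes are expressed in within-group SD units for
expression and in delta-PSI units for splicing (converted to the logit
scale by the inverse logistic slope at the event's baseline):

- `sex_shift` — male-minus-female offset;
- `age_slope` / `interaction` — total change across the cohort age span
  (per-year slope = magnitude / span), the interaction carried by one sex;
- `breakpoint_trajectory` — flat before the breakpoint age, linear ramp
  reaching the magnitude at the oldest age;
- `sf_regulation` — target-event logit-PSI coupled to the standardized
  realized expression of a regulator gene.

Latent batch factors load on a random 30% of features (loading SD 0.4 in
per-feature noise units), emulating the confounding that surrogate
variables should absorb.  PSI missingness is completely at random; the
mechanism in real cohorts is unknown, so the rate is a config knob and
MCAR is the deliberate neutral default.  Ages are uniform integers over
the configured range (default 20–79); donors are sampled per tissue.

What the generator does **not** emulate: read-level sampling noise,
length/GC biases, correlated gene programs beyond the planted blocks,
non-linear SF dose-response, and informative missingness.  Passing tests
therefore demonstrate the statistical machinery recovers planted
structure under idealized noise — not pipeline performance on any real
cohort.

## Preprocessing

Order: sample filter → gene filter → event filter → imputation.  Sample
removal changes every per-event statistic, so it comes first.  Samples
missing PSI in more than 50% of events are dropped; genes with average
TPM < 1 are dropped; a splice event must satisfy all seven criteria
(missingness < 5%, mean junction support > 10 reads, non-constant PSI,
range > 0.05, SD > 0.01, mean PSI in [0.05, 0.95], host gene average
TPM > 1), with the first failing rule recorded per event.  Inequalities
are strict exactly as written.  Missing PSI is imputed by k-nearest
samples (Euclidean distance over jointly observed events, uniform-weight
mean, k = 10 default, clamped to [0, 1]); observed entries are never
altered.  Brain tissues are merged into per-donor functional-region
pseudo-samples by arithmetic averaging of member-region values.

The scaling normalization divides each centered feature by its average
absolute deviation, `norm(y) = (y − mean y) / mean|y − mean y|`, putting
TPM and PSI on one scale while down-weighting heavy tails relative to an
SD-based z-score.

## pcSVR

For two groups embedded in the PC subspace capturing > 80% of variance
(smallest prefix; other cutoffs supported),

    pcSVR = ||X̄ − Ȳ||₂ / sqrt(σ²_X/N_x + σ²_Y/N_y),

with σ² the mean squared distance of members to their group centroid
(denominator N − 1).  With one PC this is the classical two-sample SNR.
PCA centers but does not rescale features, because inputs are already
AveDis-normalized (GE matrices are log2(TPM+1) by default).

The empirical p-value subsamples half the smaller group per side, refits
PCA per draw, and averages the statistic over draws; the null repeats
equal-sized label-free draws (without replacement, or with replacement
for the bootstrap variant) split randomly into pseudo-groups, and the
p-value is the fraction of null draws strictly above the observed mean.
**Calibration caveat**: because the observed side is an average while
each null value is a single draw, the null p-value distribution is
under-dispersed (concentrated near 0.5) rather than uniform.  The test
is conservative — at the screening cutoff 0.1 the measured type-I rate
is ≈ 1% — so significant calls are trustworthy, but p-values should not
be treated as uniform under the null.  Age contrasts compare young
(< 40) vs old (> 60) donors; strata need at least 4 samples per group.

## Differential models

Per feature, ordinary least squares of the AveDis-normalized value on
intercept, sex (F = 0, M = 1), age in years, sex×age, and surrogate
variables; all features share a design, so the fits are computed by one
factored solve (statsmodels OLS is the per-feature oracle in the tests).
Surrogate variables are the leading right-singular vectors of the
residual matrix after regressing out the primary design; their number is
chosen by parallel analysis (raw rows permuted, re-residualized, and a
component kept while its singular value exceeds the permutation 95th
percentile for its rank — measured to select k = 0 in 19/20 null
datasets while recovering a planted batch factor at |r| > 0.9).
Diagnostics report SV correlations with known covariates (point-biserial
for binary, Spearman otherwise).

Differential calls gate a coefficient p-value < 0.05 with a raw-scale
effect: direction-symmetric group-mean fold change > 1.5 for expression
or |delta PSI| > 0.05 for splicing, with groups old/young for age and
M/F for sex effects; a pseudocount guards zero group means.  Fold
changes use raw group means (not model coefficients) because the
thresholds live on the raw scale.  The permutation audit shuffles sex
and age jointly as one donor-label permutation; per-feature FDR is the
fraction of permutations in which the feature is re-called, and the
per-iteration overlap fraction tracks how much of the original call set
each permutation reproduces.  No additional multiplicity adjustment is
applied beyond these permutation metrics — the fixed p + effect-size
gates are the decision rule.

Sex-stratified fits regress on age within each sex (SVs re-estimated per
stratum; strata under 10 samples are skipped).  Features significant in
exactly one sex are sex-biased (sBASEs for splice events); in both,
sex-ubiquitous.  Set overlaps use the hypergeometric upper tail; female
vs male age-coefficient agreement uses Spearman correlation, and two
correlations are compared by Fisher's z.

## Splicing-factor networks

An SF→event edge requires all three evidences: Spearman correlation of
SF TPM with event PSI (p < 0.05, per sex, ≥ 5 samples, constant SF rows
skipped); a control-vs-shRNA regression coefficient significantly
non-zero (≥ 2 replicates per arm); and a localized motif signal in the
sliding-window binding-score profile (window 40 nt, step 1 nt over the
±300 nt splice-site flanks): maximum score > 1 and a two-sided Wilcoxon
rank-sum p < 0.05 between the highest- and lowest-mean bins of 20
consecutive window scores.  A bin is 20 *scores* (not nucleotides)
because the test needs per-bin observations.  Exact rank-sum enumeration
is used when there are no ties and sizes permit; otherwise the normal
approximation with tie correction.  The max-score criterion is applied
per event (per-site available via the profile layout).

## Aging-rate curves and breakpoints

Surrogate-variable contributions are subtracted (sex and age effects
preserved) and samples averaged per (sex, age in whole years).  The
per-age trajectories are screened by ARIMA model selection — exhaustive
AIC minimization over non-seasonal orders p, d, q ≤ 2, intercept only
for d = 0 — keeping features whose best model is integrated (d ≥ 1) with
positive total |AR| + |MA| coefficient mass ("chronological" features).
The bounded exhaustive grid replaces a stepwise search; at trajectory
lengths of 40–60 points it evaluates every candidate the stepwise
heuristic could reach.

The aging rate at age i and window span w ∈ [5, 15] years compares
observations aged in (i−w, i] vs (i, i+w] (half-open bins; ≥ 3 per
flank) by a two-group MANOVA on the top-3 PC scores of the
chronological-feature submatrix, PCA fit once per stratum so per-age
statistics share a basis.  For two groups every MANOVA statistic is a
monotone function of Hotelling's T², so the Pillai-trace F test is
computed in closed form (statsmodels MANOVA is the oracle in tests).
Per-span −log10 p series are LOESS-smoothed (degree 1) at bandwidths
0.25–0.75 step 0.05, averaged, re-smoothed at bandwidth 0.5, and
averaged across spans; the pre-smoothing span-averaged series is kept
alongside.  Breakpoints are the global maximum of the curve (earliest
age on ties) plus local maxima whose height above the nearest local
minimum exceeds 10% of the global maximum; endpoints are never
candidates.  Female and male curves are compared by an exact Wilcoxon
signed-rank test on the shared age grid, and each sex's major breakpoint
is the global-maximum age.

## Aging-modulated genes (AMGs)

200 iterations each remove a random 20% of the chronological set,
recompute the rate curve, and test whether it changed (two-sided
Wilcoxon signed-rank, p < 0.05); per gene, a one-sided Fisher exact test
asks whether its removal is enriched among curve-altering iterations
(AMG if p < 0.05).  Two design choices matter:

1. The per-iteration comparison uses the **unsmoothed** per-age rates
   restricted to ±4 years of the original curve's breakpoints (detected
   on the unsmoothed curve, since heavy smoothing can merge nearby
   peaks).  Comparing full smoothed curves makes the scale-free
   signed-rank fire on the tiny sign-consistent wiggles that *any*
   feature removal induces (measured 65–80% "significant" iterations
   for background-only removals), which destroys the enrichment signal;
   full-curve pairing remains available via `compare="full_curve"`.
2. The procedure can only discover **non-redundant** rate drivers.  If k
   interchangeable features carry a signal, the PC-score
   signal-to-noise is nearly invariant to dropping one of them, so no
   single gene's removal alters the curve.  Synthetic validations
   therefore plant drivers that are sole carriers of their breakpoints;
   genes inside large redundant programs are invisible to this test by
   construction, a limitation inherited from the definition of an AMG.

Expression patterns of AMGs are classified on fitted trajectories over
nine 5-year age windows (20–25, 26–30, …, 61–65): "up at young" when
the mean over ages 31–40 strictly exceeds that over 20–30, and
"monotone decline" when window means never increase.

## Numerical and degenerate-input conventions

Constant feature rows are errors for scaling (AveDis = 0) and skipped in
correlations; empirical p-values of 0 carry a stored resolution bound of
1/n_iter; subsample sizes round down; strict inequalities follow the
printed thresholds throughout; LOESS fractions are clamped so each fit
sees at least two points; Wilcoxon tests drop zero differences and use
the exact distribution for ≤ 30 pairs; identical paired curves are
reported as "no difference" rather than an error.

## Problem sizes in the shipped validations

The test-suite cohorts use 30–300 features and 60–300 donors, rate
curves use per-age trajectories over 60 ages or 240-sample strata, and
the disturbance analysis uses the prescribed 200 iterations on a 50-gene
set — sizes at which every planted structure above is comfortably
identifiable while the full suite remains quick to run.
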