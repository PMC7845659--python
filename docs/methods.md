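# Methods

This note documents the models, numerical choices and limitations of
`ssripgx`. It is the package's own account of its science; every number
quoted here is computed by the test suite or `scripts/acceptance.py`.

## Phenotype derivation

The four treatment-response phenotypes are deterministic functions of the
HRSD-21 trajectory. Boundary behaviour is fixed as follows and enforced by
tests: a week-8 total of exactly 7 counts as remitted (the rule is "greater
than 7" for non-remission); a reduction of exactly 50% at week 4 counts as
response (the rule is "less than 50%" for non-response); item 1 of exactly 3
counts as stem-depressed. %ΔHRSD is kept signed, so negative values mean
improvement. The continuous %ΔHRSD index is taken at week 4, consistent with
the binary response definition; the week is a parameter of nothing — it is a
fixed design choice, flagged here because the alternative (week 8) is also
defensible. Phenotypes are always computed on observed data first; imputed
phenotypes exist only inside the multiple-imputation stack, where completed
totals are re-coded through the same single-sourced rules.

## Synthetic trial generator

The generator is the test bed for the whole pipeline and emulates a
two-centre SSRI trial: cohort A with 253 subjects (17.4% male, age
41.0 ± 13.7) and cohort B with 175 (45.1% male, age 47.4 ± 15.1).

**Genotypes.** Haplotypes are drawn from independent LD blocks; within a
block every variant shares one latent standard-normal factor with weight
√ρ (default ρ = 0.8), and an allele is present when the latent value falls
below the normal quantile of the variant's target allele frequency (uniform
on [0.05, 0.5] by default). Two haplotypes per subject are summed and each
variant is oriented so the alt allele is minor. This is the simplest
mechanism with tunable pairwise r², which is what the pruning and Meff
machinery needs; it does not produce realistic recombination-driven LD decay.

**Trajectories.** Baseline totals are 14 + Poisson(7) (the trial's inclusion
criterion is a baseline of at least 14). Each subject improves by the
fraction F·(week/8)^s of baseline, F ~ N(0.545, 0.19²) clipped to [0, 1]
and shifted additively by per-allele causal effects (and optional sex/age
terms); s = 0.30; visit noise is N(0, 2) points. These four defaults were
calibrated once, by simulation at 4,000 subjects, to the targeted outcome
marginals — ~33% week-8 remission, ~39% week-4 response, ~60% week-8
response, ~11% moderately-severe-or-worse depressed mood at week 4 — and
then frozen. Totals are spread over the 21 items by largest-remainder
allocation against fixed weights (the item maxima), with item 1's weight
raised to 9.7 so stem-depressed severity is controllable; only item 1 and
the total matter downstream.

**Missingness.** Each subject's pattern is drawn once: complete / one of
weeks 2, 4, 8 missing / two-plus missing, with default probabilities
(0.92, 0.07, 0.01). Baseline is never removed. Within "two-plus", two
visits are dropped with probability 0.8 and all three with 0.2 — the
published source for the pattern frequencies gives only the three marginal
probabilities, so this split is a free choice. Missingness is
pattern-level MCAR; the generator does not emulate dropout that depends on
symptom severity, so imputation tests validate correctness under MCAR, not
robustness to informative missingness.

## Multiple imputation

"Impute, estimate, pool": incomplete visit totals are filled by chained
normal linear regressions on baseline, age, sex and the other (current)
totals, sweeping the incomplete columns for 4 cycles; each missing cell gets
the regression prediction plus a residual draw from N(0, σ̂²), so subjects
with identical predictors receive distinct values and the natural
variability is preserved. The procedure is repeated m = 30 times (both m and
cycles configurable). Regression coefficients are not themselves redrawn
between imputations ("improper" imputation in Rubin's terminology); with
the package's moderate missingness (~8% of subjects missing any visit) the
pooled-inference tests show nominal behaviour, but users should expect
slightly anticonservative between-imputation variance at high missingness.
Binary phenotypes are imputed on the continuous total-score scale and
re-coded, keeping the coding rules in one place. Pooling follows Rubin's
rules: T = W̄ + (1 + 1/m)B, df = (m − 1)(1 + W̄/((1 + 1/m)B))², with B
defined as 0 for m = 1 and B snapped to 0 when the estimates are identical
to machine rounding.

## Quality control

The Hardy–Weinberg test is the standard two-sided exact conditional test:
heterozygote counts of the observed parity are enumerated in log-space and
the p-value sums all configurations no more probable than the observed one
(tie tolerance 1 + 1e-12 in probability ratio); the suite verifies exact
agreement with rational-arithmetic enumeration for every count triple with
total ≤ 50. Marker filters: HWE p > 1e-4 (strict), missing rate ≤ 5%
(inclusive), MAF ≥ 0.05 (inclusive). Sample filters: call rate strictly
above 97%; kinship screening on pairwise IBS distance (pairs closer than a
configurable 0.1 drop the lower-call-rate member — the source procedure
names no numeric cutoff, so the default is exposed, not asserted);
population outliers from classical Torgerson MDS of the IBS distance matrix,
flagged beyond 6 MADs on any leading component. Plate-level genotyping-bias
checks are reduced to per-sample call rate because plate metadata is not
modelled.

## Single-marker association

Additive dosage (0/1/2 minor-allele copies, oriented on the analysis
sample), OLS for continuous and maximum-likelihood logistic for binary
phenotypes, age and sex as covariates, two-sided Wald tests, complete-case
per variant. The {1, 2} phenotype codes map to events as: remitted = 2,
response = 1, stem-depressed = 1, so an OR above 1 means the minor allele
favours the clinically better outcome for remission/response. Perfect
separation or non-convergence yields a `not_converged` status with missing
statistics rather than an exception; monomorphic dosages are flagged.
Difference tests are the pooled-variance two-sample t-test and the Pearson
chi-square without continuity correction.

## Gene-based test

Mapping uses 1-based inclusive windows [start − 50 kb, end + 50 kb].
Pruning is greedy in ascending position order (not p-value order), so the
retained set depends only on genotypes and is identical across permutations.
The statistic is the truncated Fisher sum T = Σ(−2 ln p) over retained
markers with p < 0.1; the entry truncation is phenotype-dependent and is
re-applied inside every permutation. The "LD correction" is implicit in the
null: permutations shuffle the subject labels of the whole genotype block,
leaving the phenotype–covariate pairs and the inter-marker correlation
intact, so the null distribution of T automatically reflects the local LD.
The empirical p-value is the add-one estimator (1 + b)/(K + 1) with
exceedance T_perm ≥ T_obs (K = 50,000 by default; an optional adaptive
early stop is off by default).

Two numerical choices matter. First, marker p-values inside the permutation
loop use closed forms: the exact OLS partial t-test (identical to the Wald
test) for linear phenotypes, and the Rao efficient-score test for logistic
phenotypes, whose covariate-only fit is done once because permutations never
change the phenotype–covariate relationship. Second, a truncated sum has
positive probability of T = 0 (no marker under the entry threshold); if
zero-zero ties counted as exceedances, null empirical p-values would carry
an atom at 1 and fail uniformity. Zero-sum ties are therefore ordered by
the smallest marker p-value — a monotone refinement of the statistic that
leaves it unchanged whenever any marker contributes and restores exact
calibration (verified by KS test over 500 simulated null genes). Missing
genotype calls are mean-imputed per variant inside this module so that the
statistic is a fixed function of the genotype block.

## Combination across cohorts

Inverse-gamma combination with shape α transforms each p to the Gamma(α, 1)
upper-tail quantile, sums, and evaluates the Gamma(kα, 1) upper tail; α = 1
is exactly Fisher's method, and the k = 1 identity and χ²(2k) closed form
are tested to 1e-12 relative tolerance. Fisher combination is
direction-blind: cohorts with opposite effect signs can still combine to a
small p, so per-cohort effect estimates are carried through the report
tables for inspection. Mega-analysis pools allele-aligned genotypes
(swapped ref/alt flipped; strand flips complemented; strand-ambiguous A/T
and C/G variants dropped when MAF > 0.4) and reruns the identical
single-marker machinery; by default it adjusts for age and sex only, with a
cohort-indicator covariate available by config. Significance tiers use
strict inequalities: markers 5e-4 / 5e-3 / 1e-2, genes 1e-2 / 5e-2, and the
headline counting rule requires the threshold in *both* meta and mega
columns. The LD-adjusted Bonferroni level is α divided by the Li–Ji
effective number of tests, Meff = Σ [I(λᵢ ≥ 1) + (λᵢ − ⌊λᵢ⌋)] over the
eigenvalues of the absolute dosage correlation matrix.

## Pipeline

The orchestrated run is deterministic given the config seed (verified
byte-for-byte), logs every excluded sample/variant with a reason code, and
pools per-variant association across the imputation stack with Rubin's
rules; the gene-based permutation test runs on the first completed dataset,
a pragmatic choice (permutation tests over all m completed datasets would
multiply the dominant cost by m for little inferential gain at this
missingness level). Report tables use N (%) cells with percentages to two
decimals and mean (s.d.) cells to two decimals; gene plots write the plotted
−log10 p values as TSV alongside the image.

## Problem sizes in the validation suite

Distributional checks run at sizes chosen to make the Monte-Carlo error
small relative to the tolerance while keeping the default suite quick: 500
null genes × 999 permutations (n = 400, 20 block-LD markers) for gene-test
calibration; 200 replicates of n = 2,000 for logistic effect recovery
(mean ÔR 1.50 vs truth 1.5); n = 1,000 with 10% MCAR for imputation
accuracy; 10,000 draws for the α ≠ 1 combination-uniformity check; exact
enumeration (no sampling) for Hardy–Weinberg. The acceptance script uses
200 null genes × 499 permutations for the same calibration measurement.

## Known limitations

* The generator's LD is block-wise exchangeable, not distance-decaying, and
  its genotypes are complete; genotype-imputation workflows are out of
  scope.
* Imputation is improper (no parameter redraw) and assumes MCAR-style
  missingness; no MNAR sensitivity analysis.
* Kinship screening is plain IBS distance, not a robust estimator such as
  KING; fine for duplicates/close relatives in homogeneous samples only.
* The mixed-model structure sometimes used for repeated measures is
  approximated throughout by cross-sectional regressions on per-week totals
  with baseline as predictor.
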