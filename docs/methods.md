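# Methods

## The screening procedure

The screen treats marker robustness as stability under resampling. Given a
cohort of n patients with overall survival (time in months, death = event,
right-censoring otherwise) and a genes × patients expression matrix on a
log2, per-gene median-centered scale, it draws B random sub-cohorts
("partitions"): the size of each draw is uniform on the integers
[min_size, max_size] (defaults 50 and n) and membership is a simple random
sample without replacement. "Partition" is deliberately interpreted as
repeated subsampling rather than a disjoint split — the size range extends
to the full cohort, which no disjoint partition could produce.

Per gene and per partition a univariate Cox proportional-hazards model is
fitted with the expression covariate standardized to mean 0, SD 1 within
the partition, so every coefficient reads as a log hazard ratio per 1 SD
of expression and is comparable across partition sizes and cohorts. The
per-partition Wald p-values and coefficients are aggregated into: mean and
median coefficient, mean and median p, and the fraction of partitions with
p < alpha (default 0.05, two-sided). Both mean and median aggregates are
first-class outputs because they answer different questions (the mean is
moment-like and sensitive to unstable fits; the median matches how a
skewed p distribution is usually summarized). Partitions whose fit does
not converge are excluded from the aggregates and counted, never imputed.
The default selection rule — fraction significant ≥ 0.9 and median
partition p ≤ 0.05 — makes the informal notion "significant in the large
majority of sub-cohorts" operational; both thresholds are parameters.

Randomness is reproducible by construction: a master seed plus a stable
SHA-256 hash of the gene id seeds an independent stream per gene, so
results are identical regardless of gene order or subsetting, and a
`random_state` of None means seed 0 rather than OS entropy.

## Survival primitives

Kaplan-Meier, log-rank and Cox fitting are implemented from first
principles because the screen needs full control over tie conventions and
convergence reporting.

* Kaplan-Meier: product-limit estimate over distinct event times; subjects
  censored exactly at an event time remain at risk at that time; Greenwood
  standard errors; the median is the smallest observed event time with
  estimated survival ≤ 0.5 and is reported as undefined (NaN) when the
  curve never reaches 0.5.
* Log-rank: Mantel-Haenszel form with hypergeometric expectations and
  variances at each distinct event time; the K-sample statistic uses the
  full covariance matrix with a generalized inverse, making it exactly
  invariant under group relabeling; p from chi-square on K − 1 df. Zero
  total variance raises an error rather than returning a number.
* Cox: Newton-Raphson with step-halving on the log partial likelihood;
  Efron tie correction by default, Breslow selectable (the two coincide
  exactly when no event times tie; published glioma analyses predate a
  stated tie choice, so both are available). Convergence is declared when
  the largest score component falls below 1e-9 (max 50 iterations);
  standard errors come from the inverse observed information at the
  optimum. A monotone likelihood (e.g. perfect separation) is flagged as
  non-convergence — detected either by the coefficient passing |β| = 50 or
  by a standard error above 50 on the log-HR scale, since with a tight
  score tolerance a separated fit stalls at moderate |β| with an enormous
  SE — and Wald summaries refuse non-converged fits. Wald inference:
  CI = exp(β ± z·SE), two-sided normal p.

## Synthetic cohorts

The generator emulates the data structure the analysis assumes; it is a
stand-in, not an estimate of any real dataset, and all of its
distributional choices are explicit parameters.

* Expression: one standard Gaussian row per gene, median-centered per gene
  (values are treated as already log2-scale). Planted prognostic genes are
  a list of (gene index, true log-HR per 1 SD).
* Survival: Weibull proportional hazards, T = λ(−log U / exp(lp))^(1/k),
  defaults k = 1.2, λ = 18 months — chosen so a covariate-free patient has
  median OS ≈ 13 months, the scale of GBM cohorts. The linear predictor
  adds the planted gene effects (on standardized expression) and covariate
  effects.
* Covariates: mutation ~ Bernoulli(0.074) with log-HR −0.97 (a rare,
  strongly favorable mutation), sex male ~ Bernoulli(0.63) with +0.10, age
  Gaussian (median 59, SD 12) acting through the ≥ 60 indicator with
  +0.55, treatment ~ Bernoulli(0.5) with −0.50. These echo the qualitative
  covariate structure of published GBM tables (rare favorable mutation
  around 7%, age effect HR ≈ 1.7, male excess ≈ 63%); they are defaults,
  not fitted values.
* Censoring: independent exponential with rate solved by root-finding so
  that, given the realized latent event times, the expected censored
  fraction equals the target (default 0.177, i.e. ≈ 82% events). The
  calibration is exact in expectation, so realized fractions vary only
  binomially (SD ≈ 1.2 pp at n = 1000). A target of 0 disables censoring;
  an unreachable target raises a calibration error. The achieved censoring
  stored in the truth record is the exact realized fraction of
  event-indicator zeros.
* Methylation: beta = expit(a − b·z + ε) with z the linked gene's
  standardized expression and ε Gaussian (SD 1 by default); b is solved by
  bisection so the realized Pearson correlation with the expression row
  hits the target (default −0.59) essentially exactly. Values lie in
  (0, 1) by construction; with SD-1 noise the reachable |r| tops out
  around 0.79, and unreachable targets raise a calibration error.

What the generator does not emulate — platform/batch effects, expression
correlation structure between genes, transcriptional subtypes, copy
number, non-proportional hazards, informative censoring — bounds what
passing tests show: they validate the statistical machinery under the
stated model, not performance on any real cohort.

## Downstream analyses

Dichotomization sends values ≤ the median to the low group (the tie
convention is one line and documented; under it the group imbalance is at
most twice the number of values tying the median). The lower-tertile rule
puts the ⌊n/3⌋ smallest values in the low group, ties broken by stable
patient-id order. All-identical values are rejected — no cut exists.

The multivariate model keeps expression continuous (per-SD, stated in the
output header), codes mutation/sex/age≥cutoff as 0/1 indicators (age
cutoff 60 by default, configurable), drops patients with any missing
covariate and reports the dropped count. Subgroup analyses (treated,
untreated, mutation-wild-type) recompute the dichotomization within the
subset, matching the convention of analysing each sub-cohort on its own
scale. Methylation association reports, per probe, Pearson r with the
exact t-test t = r√(n−2)/√(1−r²) and a Mann-Whitney comparison of beta
values between expression groups (scipy's implementation: exact
enumeration for small untied samples, tie-corrected normal approximation
otherwise). Cohort summaries exclude missing values from percentage
denominators and display one decimal, or two when the percentage is below
10; rounding is display-only. Cross-cohort homogeneity uses chi-square on
grade counts (with an exact fallback noted when a 2×2 table has an
expected cell < 1), Kruskal-Wallis on age, Fisher's exact (two cohorts) or
chi-square (more) on sex, and the K-sample log-rank on OS.

Expression normalization offers log2-then-median-center (the numerically
natural order) and a ratio-to-median-then-log2 toggle; subtractive
centering before the log is ill-posed (non-positive values), and for an
odd patient count the two offered orders coincide exactly because an
observed median commutes with the logarithm.

## Problem sizes and numerical choices

Simulation-backed tests run at deliberately chosen scales: the screen's
type-I error is estimated by averaging the significant-partition fraction
over 100 null gene-cohort pairs at the full study design (n = 424, B =
500) because a single gene's fraction is heavily dispersed across cohorts
(the partitions of one cohort are correlated through its realized effect);
power uses 50 independent planted cohorts; parameter recovery uses 200
cohorts of n = 400 with no covariate effects so the univariate fit is
correctly specified (with omitted covariates the marginal Cox coefficient
is attenuated — non-collapsibility — which is a property of the model, not
an estimator defect). Cross-checks against the reference survival
implementation cover 50 random instances of n ≤ 50 with up to 3
covariates; the reference is occasionally re-converged from our solution
because its optimizer can stop ~1e-6 short of the optimum at its own
default stopping rule.

Known limitations: no time-varying covariates, frailty, or
proportional-hazards diagnostics; no penalized or joint genome-wide
models; the screen's partition draws are independent across genes by
design (a shared-partition variant would correlate gene summaries and is
not implemented); p-value aggregation across overlapping subsamples has no
closed-form null distribution — the fraction-significant statistic is
calibrated empirically, which is exactly what the simulation suite does.
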