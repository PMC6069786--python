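# coxscreen

Resampling-based screening of prognostic gene-expression markers for
survival cohorts, with the downstream stratification and methylation
analyses used in high-grade glioma (HGG) biomarker studies.

## The problem

Single-gene prognostic markers found by fitting one Cox model per gene on
one cohort replicate poorly: glioma cohorts are heterogeneous in size, case
mix and platform, and a gene that is significant on the full cohort may owe
that significance to a particular sub-population. `coxscreen` implements a
random-partitioning robustness screen: the cohort of *n* patients is
subsampled *B* times (default *B* = 500), each subsample's size drawn
uniformly from [50, *n*] and its members drawn without replacement, so each
draw emulates a plausible smaller study. For every gene *g* and subsample
*b*, a univariate Cox proportional-hazards model

> h(t | x) = h₀(t) · exp(β_g · x_g),  x_g standardized, so HR = exp(β_g) is per 1 SD of expression

is fitted by Newton–Raphson on the partial likelihood (Efron or Breslow tie
handling), and the per-partition coefficients and Wald p-values are
aggregated: mean and median of β and p, plus the fraction of partitions
with p < α. A robust marker is one that stays significant in nearly all
partitions (default rule: fraction ≥ 0.9 and median partition p ≤ 0.05),
not just on the full cohort.

Around the screen the package provides, from first principles where the
statistics are its core business: Kaplan-Meier estimation (Greenwood SEs,
median survival), the K-sample log-rank test, multivariate Cox adjustment
(mutation status, sex, age dichotomized at 60), treated/untreated and
mutation-wild-type subgroup analyses, promoter-methylation association
(Pearson r with its exact t-test, Mann-Whitney group comparison), and
Table-1-style cohort summaries with cross-cohort homogeneity tests.

Because the real consortium downloads (TCGA, Rembrandt, GEO) are outside
desk scale, the package ships a first-class synthetic-cohort generator:
Weibull proportional-hazards survival with calibrated exponential
censoring, planted prognostic genes among nulls, a GBM-like covariate mix
(~7% favorable mutation, sex, age, treatment flag), and methylation beta
values anti-correlated with a linked gene's expression at a calibrated
Pearson r. Every analysis is therefore testable end to end with no
download.

## Worked example

```python
import numpy as np, pandas as pd
from coxscreen import (SimulationConfig, generate_cohort, PartitionCoxScreen,
                       dichotomize, stratified_km, select_robust)

cfg = SimulationConfig(n_patients=424, n_genes=50,
                       planted_genes=((12, float(np.log(1.4))),),   # per-SD HR 1.4
                       methylation_targets=(("cg0001", 12, -0.59),),
                       censoring_target=0.177, seed=0)
clinical, expression, methylation, truth = generate_cohort(cfg)
t = clinical["os_months"].to_numpy()
e = (clinical["vital_status"] == "Dead").to_numpy().astype(float)

screen = PartitionCoxScreen(b=500, min_size=50, random_state=0)
screen.fit(expression.T, (t, e))
print(screen.summary_.head(3).round(4))
print(select_robust(screen.summary_))
```

prints (the planted gene is column 12, id `G0013`):

```
         coef      hr       p  coef_mean  p_median  fraction_significant
gene
G0013  0.3226  1.3808  0.0000     0.3176    0.0000                  0.93
G0047 -0.1154  0.8910  0.0241    -0.1153    0.0829                  0.36
G0041  0.1096  1.1159  0.0425     0.1114    0.1101                  0.26
['G0013']
```

The planted gene is recovered with a full-cohort per-SD HR of 1.38 (truth
1.4) and stays significant in 93% of the 500 partitions; the two runner-up
null genes clear p < 0.05 on the full cohort but survive only a third of
partitions — exactly the instability the screen is built to expose.
Stratifying on the robust gene:

```python
assign = dichotomize(pd.Series(expression.loc["G0013"].to_numpy(),
                               index=clinical["patient_id"]))
rep = stratified_km(t, e, assign, ids=clinical["patient_id"].to_numpy())
print(rep.median_low, rep.median_high, rep.logrank.pvalue)
```

gives median overall survival of 14.0 months (low-expression group) versus
11.1 months (high), log-rank p = 9.9e-05, and the calibrated methylation
probe shows Pearson r = −0.59 with higher beta values in the low-expression
group — the promoter-silencing pattern the generator emulates.

The same pipeline is scriptable from the shell
(`coxscreen simulate / screen / stratify / adjust / subgroup / methylation /
summarize / compare / run`); `coxscreen run --config cfg.yaml --seed 0
--out reports/` executes simulate → screen → stratify → methylation →
summarize and writes TSV reports whose header lines embed all parameters,
the seed and the package version.

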