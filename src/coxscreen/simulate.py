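"""Synthetic high-grade-glioma-like survival cohorts.

The generator emulates the statistical structure the screening pipeline
assumes: a genes x patients log-scale, median-centered expression matrix
with a handful of truly prognostic genes among many nulls; overall survival
drawn from a Weibull proportional-hazards model with independent exponential
right-censoring calibrated to a target censored fraction; clinical
covariates with the qualitative mix of a GBM cohort (rare favorable
mutation ~7%, sex, age dichotomised at 60, a treatment flag); and promoter
methylation beta values anti-correlated with a linked gene's expression
through a noisy inverse-logit link calibrated to a target Pearson r.

Nothing here is estimated from real data: the distributional choices are
explicit stand-ins whose parameters are exposed on :class:`SimulationConfig`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit


class CalibrationError(RuntimeError):
    """A censoring-rate or methylation-slope calibration target is unreachable."""


@dataclass(frozen=True)
class SimulationConfig:
    """Generating parameters for one synthetic cohort.

    planted_genes: (gene index, true log hazard ratio per 1 SD of expression).
    covariate_effects: log hazard ratios for mutation (mutant vs wild-type),
    sex (male vs female), age (>= age_cutoff vs below), treatment (yes vs no).
    baseline_shape/baseline_scale: Weibull baseline hazard, time in months.
    censoring_target: intended censored (alive) fraction.
    methylation_targets: (probe id, gene index, target Pearson correlation
    between beta values and that gene's expression).
    """

    n_patients: int = 424
    n_genes: int = 100
    planted_genes: tuple = ()
    covariate_effects: dict = field(
        default_factory=lambda: {
            "mutation": -0.97,  # ~ HR 0.38, favorable
            "sex": 0.10,
            "age": 0.55,  # ~ HR 1.74 for age >= cutoff
            "treatment": -0.50,
        }
    )
    mutation_frequency: float = 0.074
    sex_male_prob: float = 0.63
    treatment_prob: float = 0.5
    grade_iii_fraction: float = 0.0
    age_median: float = 59.0
    age_spread: float = 12.0
    age_cutoff: float = 60.0
    baseline_shape: float = 1.2
    baseline_scale: float = 18.0
    censoring_target: float = 0.177
    methylation_targets: tuple = ()
    methylation_noise_sd: float = 1.0
    methylation_intercept: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        for p in ("mutation_frequency", "sex_male_prob", "treatment_prob",
                  "grade_iii_fraction", "censoring_target"):
            v = getattr(self, p)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{p} must be in [0, 1], got {v}")
        if self.censoring_target >= 1.0:
            raise ValueError("censoring_target must be < 1")
        if self.baseline_shape <= 0 or self.baseline_scale <= 0:
            raise ValueError("Weibull baseline shape and scale must be > 0")
        for g, _ in self.planted_genes:
            if not 0 <= g < self.n_genes:
                raise ValueError(f"planted gene index {g} out of range")
        for probe, g, r in self.methylation_targets:
            if not 0 <= g < self.n_genes:
                raise ValueError(f"methylation target gene index {g} out of range")
            if not -1.0 <= r <= 1.0:
                raise ValueError(f"target correlation for {probe} outside [-1, 1]")
        if self.methylation_noise_sd <= 0:
            raise ValueError("methylation_noise_sd must be > 0")


@dataclass
class SyntheticTruth:
    """Ground truth kept alongside a simulated cohort for recovery tests."""

    config: SimulationConfig
    censoring_rate: float
    achieved_censoring: float
    achieved_methylation_r: dict
    methylation_slopes: dict
    latent_event_times: np.ndarray

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self.config)
        d["planted_genes"] = [list(x) for x in self.config.planted_genes]
        d["methylation_targets"] = [list(x) for x in self.config.methylation_targets]
        return {
            "config": d,
            "censoring_rate": self.censoring_rate,
            "achieved_censoring": self.achieved_censoring,
            "achieved_methylation_r": dict(self.achieved_methylation_r),
            "methylation_slopes": dict(self.methylation_slopes),
            "latent_event_times": [float(t) for t in self.latent_event_times],
        }


class CohortBundle(NamedTuple):
    clinical: pd.DataFrame
    expression: pd.DataFrame
    methylation: pd.DataFrame
    truth: SyntheticTruth


def _calibrate_censoring_rate(latent_t: np.ndarray, target: float) -> float:
    """Exponential censoring rate such that E[censored fraction | T] = target.

    Given the realized latent event times T_i and C ~ Exp(rate), the expected
    censored fraction is mean_i(1 - exp(-rate * T_i)); solve for rate.
    """
    if target == 0.0:
        return 0.0

    def f(rate):
        return float(np.mean(-np.expm1(-rate * latent_t))) - target

    lo, hi = 1e-12, 1.0 / max(np.mean(latent_t), 1e-12)
    for _ in range(200):
        if f(hi) > 0:
            break
        hi *= 2.0
    else:
        raise CalibrationError(f"censoring target {target} unreachable")
    return float(brentq(f, lo, hi, xtol=1e-12, rtol=1e-12))


def _calibrate_methylation(z: np.ndarray, x: np.ndarray, eps: np.ndarray,
                           a: float, target: float) -> tuple[np.ndarray, float]:
    """Beta values expit(a - b z + eps) with slope b solved to hit target r.

    z is the linked gene's standardized expression, x the raw (centered)
    expression against which the correlation target is defined, eps a fixed
    Gaussian noise draw. The realized correlation is monotone decreasing in
    b, so bisection on b hits the target essentially exactly.
    """

    def realized(b):
        beta = expit(a - b * z + eps)
        sd = beta.std()
        if sd == 0:
            return 0.0
        return float(np.corrcoef(beta, x)[0, 1])

    bmax = 200.0
    lo, hi = -bmax, bmax
    if not (realized(hi) - target) * (realized(lo) - target) < 0:
        raise CalibrationError(
            f"methylation correlation target {target} unreachable with the "
            "configured noise level"
        )
    b = float(brentq(lambda bb: realized(bb) - target, lo, hi, xtol=1e-10))
    return expit(a - b * z + eps), b


def generate_cohort(config: SimulationConfig, seed=None) -> CohortBundle:
    """Simulate one cohort: clinical table, expression, methylation, truth.

    Event times follow a Weibull proportional-hazards model,
    T = scale * (-log U / exp(lp))^(1/shape), with linear predictor
    lp = sum(planted beta * standardized expression) + covariate effects.
    Identical config and seed produce bit-identical output.
    """
    config.validate()
    if seed is not None:
        config = dataclasses.replace(config, seed=int(seed))
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n, g = config.n_patients, config.n_genes

    patients = [f"P{i + 1:04d}" for i in range(n)]
    genes = [f"G{j + 1:04d}" for j in range(g)]

    # expression: standard normal per gene, then median-centered per gene
    # (values are treated as already on log2 scale)
    expr = rng.standard_normal((g, n))
    expr = expr - np.median(expr, axis=1, keepdims=True)

    age = config.age_median + config.age_spread * rng.standard_normal(n)
    age = np.clip(age, 10.0, 95.0)
    male = rng.random(n) < config.sex_male_prob
    treated = rng.random(n) < config.treatment_prob
    mutant = rng.random(n) < config.mutation_frequency
    grade_iii = rng.random(n) < config.grade_iii_fraction

    eff = config.covariate_effects
    lp = np.zeros(n)
    lp += eff.get("mutation", 0.0) * mutant
    lp += eff.get("sex", 0.0) * male
    lp += eff.get("age", 0.0) * (age >= config.age_cutoff)
    lp += eff.get("treatment", 0.0) * treated
    for j, beta in config.planted_genes:
        x = expr[j]
        lp += beta * (x - x.mean()) / x.std()

    u = rng.random(n)
    latent_t = config.baseline_scale * (-np.log(u) / np.exp(lp)) ** (1.0 / config.baseline_shape)

    rate = _calibrate_censoring_rate(latent_t, config.censoring_target)
    if rate > 0:
        cens_t = rng.exponential(1.0 / rate, size=n)
    else:
        cens_t = np.full(n, np.inf)
    event = (latent_t <= cens_t).astype(int)
    os_months = np.minimum(latent_t, cens_t)
    os_months = np.maximum(os_months, 1e-3)  # times must stay > 0

    clinical = pd.DataFrame(
        {
            "patient_id": patients,
            "os_months": os_months,
            "vital_status": np.where(event == 1, "Dead", "Alive"),
            "age": age,
            "sex": np.where(male, "male", "female"),
            "grade": np.where(grade_iii, "III", "IV"),
            "treatment": np.where(treated, "yes", "no"),
            "mutation": np.where(mutant, "mutant", "wild-type"),
        }
    )
    expression = pd.DataFrame(expr, index=pd.Index(genes, name="gene_id"),
                              columns=patients)

    meth_rows, achieved_r, slopes = {}, {}, {}
    for probe, j, target in config.methylation_targets:
        x = expr[j]
        z = (x - x.mean()) / x.std()
        eps = config.methylation_noise_sd * rng.standard_normal(n)
        beta_vals, b = _calibrate_methylation(
            z, x, eps, config.methylation_intercept, target
        )
        meth_rows[probe] = (genes[j], beta_vals)
        achieved_r[probe] = float(np.corrcoef(beta_vals, x)[0, 1])
        slopes[probe] = b
    methylation = pd.DataFrame(
        {p: v for p, (_, v) in meth_rows.items()}, index=patients
    ).T
    methylation.index.name = "probe_id"
    methylation.insert(0, "gene_id", [meth_rows[p][0] for p in methylation.index])

    truth = SyntheticTruth(
        config=config,
        censoring_rate=rate,
        achieved_censoring=float(np.mean(event == 0)),
        achieved_methylation_r=achieved_r,
        methylation_slopes=slopes,
        latent_event_times=latent_t,
    )
    return CohortBundle(clinical, expression, methylation, truth)


def generate_multi_cohorts(configs, master_seed=None) -> list[CohortBundle]:
    """Simulate several independent cohorts (the multi-dataset study design).

    With a master seed, per-cohort seeds are derived deterministically so the
    cohorts are independent and reproducible regardless of list order
    changes elsewhere.
    """
    configs = list(configs)
    if not configs:
        raise ValueError("at least one SimulationConfig is required")
    out = []
    for i, cfg in enumerate(configs):
        if master_seed is not None:
            child = int(np.random.SeedSequence([int(master_seed), i]).generate_state(1)[0])
            cfg = dataclasses.replace(cfg, seed=child % (2**31))
        out.append(generate_cohort(cfg))
    return out
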