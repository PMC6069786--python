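"""Downstream survival stratification and association analyses.

Given a screened gene, this module reproduces the analysis sequence around
it: median (or lower-tertile) dichotomization into low/high expression
groups, Kaplan-Meier curves with a log-rank comparison, multivariate Cox
adjustment for mutation status, sex and dichotomized age, treated/untreated
and mutation-wild-type subgroup analyses, promoter methylation association
(Pearson correlation with its exact t-test plus a Mann-Whitney group
comparison), and Table-1-style cohort summaries with cross-cohort
homogeneity tests.

Conventions: expression values equal to the median go to the low group; the
lower-tertile rule puts the floor(n/3) smallest values in the low group with
ties broken by stable patient-id order; missing values are excluded from
percentage denominators; age is dichotomized at 60 by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .survival import CoxFit, KMEstimate, LogRankResult, cox_fit, km_estimate, logrank_test

__all__ = [
    "GroupAssignment",
    "StratifiedKMReport",
    "AssociationResult",
    "CohortSummary",
    "dichotomize",
    "stratified_km",
    "multivariate_os_model",
    "subgroup_analysis",
    "methylation_association",
    "cohort_summary",
    "compare_cohorts",
    "format_percent",
]


@dataclass
class GroupAssignment:
    """Low/high expression labels for one gene under a stated cut rule."""

    labels: pd.Series  # values 'low'/'high', index = patient ids
    rule: str
    cut_value: float

    @property
    def low(self) -> pd.Index:
        return self.labels.index[self.labels == "low"]

    @property
    def high(self) -> pd.Index:
        return self.labels.index[self.labels == "high"]


def dichotomize(values, rule: str = "median", ids=None) -> GroupAssignment:
    """Split patients into low/high expression groups.

    median rule: values <= median go low (the tie convention). lower-tertile
    rule: the floor(n/3) smallest values go low, ties broken by stable
    patient-id order. All-identical values are rejected: no cut exists.
    """
    if isinstance(values, pd.Series):
        s = values.dropna().astype(float)
    else:
        values = np.asarray(values, dtype=float)
        idx = ids if ids is not None else range(len(values))
        s = pd.Series(values, index=idx).dropna()
    if len(s) < 2:
        raise ValueError("dichotomization needs at least two non-missing values")
    if s.nunique() == 1:
        raise ValueError("all expression values identical: no cut exists")

    if rule == "median":
        cut = float(s.median())
        labels = pd.Series(np.where(s <= cut, "low", "high"), index=s.index)
    elif rule == "lower-tertile":
        k = len(s) // 3
        if k < 1:
            raise ValueError("lower-tertile rule needs at least 3 patients")
        order = s.sort_values(kind="stable").index
        low_ids = set(order[:k])
        cut = float(s.loc[order[k - 1]])
        labels = pd.Series(
            ["low" if i in low_ids else "high" for i in s.index], index=s.index
        )
    else:
        raise ValueError(f"unknown dichotomization rule: {rule!r}")
    return GroupAssignment(labels=labels, rule=rule, cut_value=cut)


@dataclass
class StratifiedKMReport:
    km_low: KMEstimate
    km_high: KMEstimate
    logrank: LogRankResult
    median_low: float
    median_high: float
    n_low: int
    n_high: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": ["low", "high"],
                "n": [self.n_low, self.n_high],
                "median_os": [self.median_low, self.median_high],
                "logrank_chisq": self.logrank.statistic,
                "logrank_p": self.logrank.pvalue,
            }
        )


def stratified_km(time, event, assignment: GroupAssignment,
                  ids=None) -> StratifiedKMReport:
    """Per-group Kaplan-Meier estimates plus the log-rank comparison."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    if ids is not None:
        pos = {p: i for i, p in enumerate(ids)}
        sel = [pos[p] for p in assignment.labels.index]
        time, event = time[sel], event[sel]
    labels = assignment.labels.to_numpy()
    if time.size != labels.size:
        raise ValueError("survival data must align with the group assignment")
    if (labels == "low").sum() == 0 or (labels == "high").sum() == 0:
        raise ValueError("both expression groups must be non-empty")
    km_low = km_estimate(time[labels == "low"], event[labels == "low"])
    km_high = km_estimate(time[labels == "high"], event[labels == "high"])
    lr = logrank_test(time, event, labels)
    return StratifiedKMReport(
        km_low=km_low,
        km_high=km_high,
        logrank=lr,
        median_low=km_low.median,
        median_high=km_high.median,
        n_low=int((labels == "low").sum()),
        n_high=int((labels == "high").sum()),
    )


def _binary(series: pd.Series, one_level: str) -> np.ndarray:
    return (series == one_level).astype(float).to_numpy()


def multivariate_os_model(clinical: pd.DataFrame, expression,
                          covariates=("mutation", "sex", "age"),
                          age_cutoff: float = 60.0, ties: str = "efron",
                          sex_reference: str = "female") -> tuple[CoxFit, int]:
    """Joint Cox model of OS on expression plus clinical covariates.

    Expression stays continuous and is standardized (per-SD hazard ratios);
    mutation, sex and dichotomized age (>= cutoff) enter as 0/1 indicators.
    Patients with any missing covariate are dropped; the dropped count is
    returned alongside the fit.
    """
    expr = pd.Series(np.asarray(expression, dtype=float),
                     index=clinical["patient_id"].to_numpy())
    df = clinical.copy()
    df["_expr"] = expr.to_numpy()
    needed = ["_expr", "os_months", "event"] + [c for c in covariates if c != "age"]
    if "age" in covariates:
        needed.append("age")
    before = len(df)
    df = df.dropna(subset=[c for c in needed if c in df.columns])
    n_dropped = before - len(df)

    cols, names = [np.asarray(df["_expr"], dtype=float)], ["expression"]
    cols[0] = (cols[0] - cols[0].mean()) / cols[0].std()
    if "mutation" in covariates:
        cols.append(_binary(df["mutation"], "mutant"))
        names.append("mutation")
    if "sex" in covariates:
        level = "male" if sex_reference == "female" else "female"
        cols.append(_binary(df["sex"], level))
        names.append("sex")
    if "age" in covariates:
        cols.append((df["age"].to_numpy(dtype=float) >= age_cutoff).astype(float))
        names.append("age")
    if "treatment" in covariates:
        cols.append(_binary(df["treatment"], "yes"))
        names.append("treatment")
    X = np.column_stack(cols)
    event = df["event"].to_numpy(dtype=float)
    if event.sum() < 2:
        raise ValueError("fewer than two events after dropping missing covariates")
    fit = cox_fit(X, df["os_months"].to_numpy(dtype=float), event,
                  ties=ties, names=names)
    return fit, n_dropped


@dataclass
class SubgroupReport:
    rule: str
    n: int
    cox: CoxFit
    km: StratifiedKMReport


_SUBSET_RULES = {
    "treated": lambda df: df["treatment"] == "yes",
    "untreated": lambda df: df["treatment"] == "no",
    "mutation-wild-type": lambda df: df["mutation"] == "wild-type",
    "all": lambda df: pd.Series(True, index=df.index),
}


def subgroup_analysis(clinical: pd.DataFrame, expression, rule: str,
                      dichotomy: str = "median", ties: str = "efron") -> SubgroupReport:
    """Univariate Cox + stratified KM restricted to a clinical subgroup.

    The low/high dichotomization is recomputed within the subset, matching
    the convention of analysing each validation sub-cohort on its own scale.
    """
    if rule not in _SUBSET_RULES:
        raise ValueError(f"unknown subgroup rule: {rule!r}")
    expr = pd.Series(np.asarray(expression, dtype=float),
                     index=clinical["patient_id"].to_numpy())
    mask = _SUBSET_RULES[rule](clinical).to_numpy()
    sub = clinical.loc[mask]
    if len(sub) == 0:
        raise ValueError(f"subgroup {rule!r} is empty")
    time = sub["os_months"].to_numpy(dtype=float)
    event = sub["event"].to_numpy(dtype=float)
    if event.sum() < 2:
        raise ValueError(f"subgroup {rule!r} has fewer than two events")
    x = expr.loc[sub["patient_id"]].to_numpy()
    z = (x - x.mean()) / x.std()
    fit = cox_fit(z, time, event, ties=ties, names=["expression"])
    assignment = dichotomize(pd.Series(x, index=sub["patient_id"]), rule=dichotomy)
    km = stratified_km(time, event, assignment, ids=sub["patient_id"].to_numpy())
    return SubgroupReport(rule=rule, n=len(sub), cox=fit, km=km)


@dataclass
class AssociationResult:
    test: str
    statistic: float
    pvalue: float
    detail: dict


def pearson_t_test(x, y) -> AssociationResult:
    """Pearson correlation with the exact t-test, t = r sqrt(n-2)/sqrt(1-r^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("Pearson t-test needs at least 3 paired observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("undefined correlation: zero variance")
    r = float(np.corrcoef(x, y)[0, 1])
    r = min(1.0, max(-1.0, r))
    if abs(r) == 1.0:
        t, p = np.inf * np.sign(r), 0.0
    else:
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
        p = 2.0 * stats.t.sf(abs(t), n - 2)
    return AssociationResult("pearson-t", float(t), float(p),
                             {"r": r, "n": n})


def methylation_association(expression, betas: pd.DataFrame,
                            assignment: GroupAssignment) -> pd.DataFrame:
    """Per-probe association of methylation with a gene's expression.

    For each probe: Pearson r (with its exact t-test) between beta values
    and expression, and a Mann-Whitney comparison of beta values between the
    low and high expression groups. Requires >= 3 paired observations.
    """
    expr = pd.Series(np.asarray(expression, dtype=float),
                     index=getattr(expression, "index", assignment.labels.index))
    rows = []
    for probe, row in betas.iterrows():
        common = expr.index.intersection(row.index)
        x, b = expr.loc[common].to_numpy(), row.loc[common].to_numpy(dtype=float)
        pearson = pearson_t_test(x, b)
        low = row.loc[[i for i in assignment.low if i in row.index]].to_numpy(dtype=float)
        high = row.loc[[i for i in assignment.high if i in row.index]].to_numpy(dtype=float)
        mw = stats.mannwhitneyu(low, high, alternative="two-sided", method="auto")
        rows.append(
            {
                "probe_id": probe,
                "n": pearson.detail["n"],
                "r": pearson.detail["r"],
                "t": pearson.statistic,
                "p_pearson": pearson.pvalue,
                "mw_U": float(mw.statistic),
                "p_mannwhitney": float(mw.pvalue),
                "mean_beta_low": float(low.mean()),
                "mean_beta_high": float(high.mean()),
            }
        )
    return pd.DataFrame(rows).set_index("probe_id")


def format_percent(p: float) -> str:
    """Display rounding: 1 decimal, 2 decimals below 10 (e.g. 7.40, 37.5)."""
    return f"{p:.2f}" if p < 10 else f"{p:.1f}"


@dataclass
class CohortSummary:
    """Table-1-style cohort description (missing excluded from percentages)."""

    n: int
    categorical: dict  # variable -> {level: (count, percent)}
    missing: dict  # variable -> count of missing values
    age_median: float
    age_range: tuple
    median_os: float
    n_alive: int
    n_dead: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for var, levels in self.categorical.items():
            for level, (count, pct) in levels.items():
                rows.append({"variable": var, "level": level, "count": count,
                             "percent": pct, "display": f"{count} ({format_percent(pct)})"})
            rows.append({"variable": var, "level": "NA",
                         "count": self.missing.get(var, 0), "percent": np.nan,
                         "display": str(self.missing.get(var, 0))})
        rows.append({"variable": "age", "level": "median (range)",
                     "count": self.n, "percent": np.nan,
                     "display": f"{self.age_median:g} ({self.age_range[0]:g}-{self.age_range[1]:g})"})
        rows.append({"variable": "median_os_months", "level": "",
                     "count": self.n, "percent": np.nan,
                     "display": f"{self.median_os:g}"})
        return pd.DataFrame(rows)


_SUMMARY_VARS = {
    "sex": ("female", "male"),
    "grade": ("III", "IV"),
    "treatment": ("yes", "no"),
    "mutation": ("mutant", "wild-type"),
    "vital_status": ("Alive", "Dead"),
}


def cohort_summary(clinical: pd.DataFrame) -> CohortSummary:
    """Counts and percentages per categorical level, median age, KM median OS.

    Percentages use non-missing denominators; empty levels report 0 (0.0).
    """
    df = clinical
    cat, missing = {}, {}
    for var, levels in _SUMMARY_VARS.items():
        if var not in df.columns:
            continue
        col = df[var]
        if var == "vital_status":
            col = col.map(lambda v: str(v).strip().capitalize())
        nonmiss = col.dropna()
        denom = len(nonmiss)
        missing[var] = int(len(col) - denom)
        cat[var] = {}
        for level in levels:
            count = int((nonmiss == level).sum())
            pct = 100.0 * count / denom if denom else 0.0
            cat[var][level] = (count, pct)
    age = pd.to_numeric(df["age"], errors="coerce").dropna() if "age" in df.columns else pd.Series(dtype=float)
    km = km_estimate(df["os_months"].to_numpy(dtype=float),
                     df["event"].to_numpy(dtype=float)) if "event" in df.columns else None
    vs = cat.get("vital_status", {})
    return CohortSummary(
        n=len(df),
        categorical=cat,
        missing=missing,
        age_median=float(age.median()) if len(age) else float("nan"),
        age_range=(float(age.min()), float(age.max())) if len(age) else (float("nan"),) * 2,
        median_os=km.median if km is not None else float("nan"),
        n_alive=vs.get("Alive", (0, 0.0))[0],
        n_dead=vs.get("Dead", (0, 0.0))[0],
    )


def compare_cohorts(cohorts: list) -> dict:
    """Cross-cohort homogeneity tests on the raw clinical tables.

    chi-square on grade counts (exact fallback noted when expected cells
    < 1 and the table is 2x2), Kruskal-Wallis on age, Fisher's exact
    (two cohorts) or chi-square on sex, and a multi-group log-rank on OS.
    """
    if len(cohorts) < 2:
        raise ValueError("cohort comparison needs at least two cohorts")
    out: dict[str, AssociationResult] = {}

    def counts(var, levels):
        tab = []
        for df in cohorts:
            col = df[var].dropna() if var in df.columns else pd.Series(dtype=object)
            tab.append([int((col == lv).sum()) for lv in levels])
        return np.asarray(tab)

    grade = counts("grade", ("III", "IV"))
    keep = grade.sum(axis=1) > 0
    if keep.sum() >= 2 and (grade[keep] > 0).any(axis=0).all():
        tab = grade[keep]
        chi2, p, _, expected = stats.chi2_contingency(tab, correction=False)
        if (expected < 1).any() and tab.shape == (2, 2):
            _, p = stats.fisher_exact(tab)
            out["grade"] = AssociationResult("fisher-exact", float("nan"), float(p),
                                             {"table": tab.tolist(),
                                              "note": "expected cell < 1"})
        else:
            out["grade"] = AssociationResult("chi-square", float(chi2), float(p),
                                             {"table": tab.tolist()})

    ages = [pd.to_numeric(df["age"], errors="coerce").dropna().to_numpy()
            for df in cohorts if "age" in df.columns]
    ages = [a for a in ages if a.size]
    if len(ages) >= 2:
        kw = stats.kruskal(*ages)
        out["age"] = AssociationResult("kruskal-wallis", float(kw.statistic),
                                       float(kw.pvalue), {"n": [a.size for a in ages]})

    sex = counts("sex", ("female", "male"))
    keep = sex.sum(axis=1) > 0
    if not (sex[keep] > 0).any(axis=0).all():
        keep = np.zeros(len(sex), dtype=bool)  # a level absent everywhere
    if keep.sum() == 2:
        _, p = stats.fisher_exact(sex[keep])
        out["sex"] = AssociationResult("fisher-exact", float("nan"), float(p),
                                       {"table": sex[keep].tolist()})
    elif keep.sum() > 2:
        chi2, p, _, _ = stats.chi2_contingency(sex[keep], correction=False)
        out["sex"] = AssociationResult("chi-square", float(chi2), float(p),
                                       {"table": sex[keep].tolist()})

    time = np.concatenate([df["os_months"].to_numpy(dtype=float) for df in cohorts])
    event = np.concatenate([df["event"].to_numpy(dtype=float) for df in cohorts])
    group = np.concatenate([np.full(len(df), i) for i, df in enumerate(cohorts)])
    lr = logrank_test(time, event, group)
    out["os"] = AssociationResult("log-rank", lr.statistic, lr.pvalue,
                                  {"df": lr.df})
    return out
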