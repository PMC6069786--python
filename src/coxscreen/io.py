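"""Tab-separated file formats, cohort joining, and the pipeline driver.

All tables are plain TSV with a header row. The clinical table has one row
per patient (patient_id, os_months, vital_status, and optional covariates);
the expression matrix is genes x patients with a ``gene_id`` index column;
the methylation table is probes x patients with ``probe_id`` and ``gene_id``
columns followed by per-patient beta values.

Rows lacking survival time or vital status are excluded at load time and
the exclusion count is logged and returned in ``DataFrame.attrs`` — the
analysis only ever sees patients with both expression and survival data.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .simulate import CohortBundle, SimulationConfig, generate_cohort

logger = logging.getLogger("coxscreen")

MISSING_TOKENS = {"", "na", "n/a", "nan", "missing", "none", "null"}

CLINICAL_REQUIRED = ("patient_id", "os_months", "vital_status")
_VITAL_MAP = {"alive": 0, "dead": 1, "0": 0, "1": 1}


def _is_missing(v) -> bool:
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return True
    return str(v).strip().lower() in MISSING_TOKENS


def normalize_missing(s: pd.Series) -> pd.Series:
    """Map the accepted missing-value spellings to NaN (object columns)."""
    return s.map(lambda v: np.nan if _is_missing(v) else v)


def attach_event(clinical: pd.DataFrame) -> pd.DataFrame:
    """Add an integer ``event`` column derived from vital_status."""
    if "event" in clinical.columns:
        return clinical
    out = clinical.copy()
    out["event"] = [
        _VITAL_MAP[str(v).strip().lower()] for v in out["vital_status"]
    ]
    return out


def load_clinical(path) -> pd.DataFrame:
    """Load and validate a clinical TSV table.

    Rows missing os_months or vital_status are dropped; the count is logged
    and stored in ``.attrs['n_excluded']``. Duplicate patient ids are a hard
    error. vital_status parses case-insensitively ('Alive'/'Dead' or 0/1)
    into an ``event`` column (1 = death).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    for col in CLINICAL_REQUIRED:
        if col not in df.columns:
            raise ValueError(f"clinical table missing mandatory column: {col!r}")
    dup = df["patient_id"][df["patient_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate patient id: {dup.iloc[0]!r}")

    usable = ~(df["os_months"].map(_is_missing) | df["vital_status"].map(_is_missing))
    n_excluded = int((~usable).sum())
    if n_excluded:
        logger.info("load_clinical: excluded %d rows lacking survival data", n_excluded)
    df = df.loc[usable].copy()

    df["os_months"] = df["os_months"].astype(float)
    if (df["os_months"] <= 0).any():
        raise ValueError("os_months must be > 0 for analyzed rows")
    bad = [v for v in df["vital_status"] if str(v).strip().lower() not in _VITAL_MAP]
    if bad:
        raise ValueError(f"unrecognized vital_status value: {bad[0]!r}")
    df = attach_event(df)
    if "age" in df.columns:
        df["age"] = pd.to_numeric(normalize_missing(df["age"]), errors="raise")
    for col in ("sex", "grade", "treatment", "mutation", "methylation_status", "subtype"):
        if col in df.columns:
            df[col] = normalize_missing(df[col])
    df = df.reset_index(drop=True)
    df.attrs["n_excluded"] = n_excluded
    return df


def load_expression(path, normalize: str = "none") -> pd.DataFrame:
    """Load a genes x patients expression TSV.

    normalize: 'none' | 'median-center' | 'log2+median-center' (log2 first,
    the numerically sensible order) | 'median-center+log2'. Genes containing
    missing values are dropped and counted in ``.attrs['n_dropped_genes']``;
    constant genes after centering are listed in ``.attrs['constant_genes']``.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index.name = "gene_id"
    n_before = len(df)
    df = df.dropna(axis=0)
    n_dropped = n_before - len(df)
    if n_dropped:
        logger.info("load_expression: dropped %d genes with missing values", n_dropped)
    df = normalize_expression(df, normalize)
    df.attrs["n_dropped_genes"] = n_dropped
    df.attrs["constant_genes"] = list(df.index[df.nunique(axis=1) == 1])
    if df.attrs["constant_genes"]:
        logger.info("load_expression: %d constant genes flagged",
                    len(df.attrs["constant_genes"]))
    return df


def normalize_expression(df: pd.DataFrame, how: str = "none") -> pd.DataFrame:
    """Apply the requested normalization per gene row.

    'median-center' subtracts each gene's median (data already on log scale).
    'log2+median-center' takes log2 of positive intensities then subtracts the
    per-gene median of the logs. 'median-center+log2' centers on the raw scale
    as a ratio to the gene median and then takes log2 — for an odd number of
    patients this coincides with the log-first order (an observed median
    commutes with the logarithm); with an even count the two differ only
    through the interpolated median. The toggle makes the order explicit.
    """
    if how == "none":
        return df
    out = df.astype(float)
    if how == "median-center":
        return out.sub(out.median(axis=1), axis=0)
    if how not in ("log2+median-center", "median-center+log2"):
        raise ValueError(f"unknown normalization: {how!r}")
    if (out.to_numpy() <= 0).any():
        raise ValueError("log2 normalization requires strictly positive values")
    if how == "log2+median-center":
        out = np.log2(out)
        return out.sub(out.median(axis=1), axis=0)
    return np.log2(out.div(out.median(axis=1), axis=0))


def load_methylation(path) -> pd.DataFrame:
    """Load a probes x patients methylation TSV (probe_id, gene_id, betas)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index.name = "probe_id"
    if "gene_id" not in df.columns:
        raise ValueError("methylation table missing 'gene_id' column")
    missing_link = df.index[df["gene_id"].map(_is_missing)]
    if len(missing_link):
        raise ValueError(f"probe without gene link: {missing_link[0]!r}")
    betas = df.drop(columns="gene_id").astype(float)
    bad = np.argwhere((betas.to_numpy() < 0) | (betas.to_numpy() > 1))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"beta value outside [0, 1] for probe {betas.index[i]!r}, "
            f"patient {betas.columns[j]!r}"
        )
    out = betas.copy()
    out.insert(0, "gene_id", df["gene_id"])
    return out


def join_cohort(clinical: pd.DataFrame, expression: pd.DataFrame):
    """Restrict both tables to their common patients (clinical row order).

    Returns (clinical, expression, n_dropped) where n_dropped counts patients
    present in only one of the two tables.
    """
    common = [p for p in clinical["patient_id"] if p in set(expression.columns)]
    n_dropped = (len(clinical) - len(common)) + (expression.shape[1] - len(common))
    if n_dropped:
        logger.info("join_cohort: dropped %d unmatched patients", n_dropped)
    clin = clinical[clinical["patient_id"].isin(common)].reset_index(drop=True)
    expr = expression[list(clin["patient_id"])]
    return clin, expr, n_dropped


def write_cohort(outdir, bundle: CohortBundle) -> dict:
    """Write a simulated cohort to TSV files plus a JSON truth file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "clinical": outdir / "clinical.tsv",
        "expression": outdir / "expression.tsv",
        "methylation": outdir / "methylation.tsv",
        "truth": outdir / "truth.json",
    }
    bundle.clinical.to_csv(paths["clinical"], sep="\t", index=False)
    bundle.expression.to_csv(paths["expression"], sep="\t")
    bundle.methylation.to_csv(paths["methylation"], sep="\t")
    paths["truth"].write_text(json.dumps(bundle.truth.to_dict(), indent=1))
    return paths


def _report_header(stage: str, params: dict) -> str:
    items = " ".join(f"{k}={v}" for k, v in sorted(params.items()))
    return f"# coxscreen v{__version__} stage={stage} {items}\n"


def write_report(path, df: pd.DataFrame, stage: str, params: dict, index=True) -> None:
    """Write a report table with a '#' header line embedding the parameters."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_report_header(stage, params))
        df.to_csv(fh, sep="\t", index=index)


def load_config(config) -> dict:
    if isinstance(config, dict):
        return config
    with open(config) as fh:
        return yaml.safe_load(fh)


def _simulation_config(section: dict, seed) -> SimulationConfig:
    kwargs = dict(section)
    kwargs["planted_genes"] = tuple(
        (int(g), float(b)) for g, b in kwargs.get("planted_genes", ())
    )
    kwargs["methylation_targets"] = tuple(
        (str(p), int(g), float(r)) for p, g, r in kwargs.get("methylation_targets", ())
    )
    if "covariate_effects" in kwargs:
        kwargs["covariate_effects"] = dict(kwargs["covariate_effects"])
    if seed is not None:
        kwargs["seed"] = int(seed)
    return SimulationConfig(**kwargs)


def run_pipeline(config, outdir, seed=None) -> dict:
    """Run simulate/load -> screen -> stratify -> methylation -> summarize.

    ``config`` is a dict or a YAML path with a ``simulate`` section (passed
    to :class:`SimulationConfig`) or an ``inputs`` section naming the three
    TSV paths, plus optional ``screen``, ``stratify``, ``methylation`` and
    ``summarize`` sections. Reports are TSVs under ``outdir`` whose header
    line embeds stage parameters, the seed and the package version. The run
    is deterministic given the seed.
    """
    from .cohort import cohort_summary, dichotomize, methylation_association, stratified_km
    from .screen import PartitionCoxScreen

    cfg = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {"outdir": outdir, "seed": seed}

    stage = "inputs"
    try:
        if "simulate" in cfg:
            sim_cfg = _simulation_config(cfg["simulate"], seed)
            bundle = generate_cohort(sim_cfg)
            results["cohort_paths"] = write_cohort(outdir / "cohort", bundle)
            clinical = attach_event(bundle.clinical)
            expression, methylation = bundle.expression, bundle.methylation
            results["truth"] = bundle.truth
        elif "inputs" in cfg:
            paths = cfg["inputs"]
            clinical = load_clinical(paths["clinical"])
            expression = load_expression(
                paths["expression"], paths.get("normalize", "none")
            )
            methylation = (
                load_methylation(paths["methylation"]) if "methylation" in paths else None
            )
        else:
            raise ValueError(
                "pipeline config needs a 'simulate' or an 'inputs' section"
            )
        clinical, expression, n_dropped = join_cohort(clinical, expression)
        results["n_unmatched_patients"] = n_dropped
        surv = (clinical["os_months"].to_numpy(), clinical["event"].to_numpy())

        if "screen" in cfg:
            stage = "screen"
            params = dict(cfg["screen"] or {})
            if seed is not None:
                params.setdefault("random_state", int(seed))
            screen = PartitionCoxScreen(**params)
            screen.fit(expression.T, surv)
            results["screen"] = screen.summary_
            results["robust_genes"] = list(screen.feature_names_in_[screen.get_support()])
            write_report(
                outdir / "screen.tsv", screen.summary_, "screen",
                {**screen.get_params(), "seed": seed},
            )

        if "stratify" in cfg:
            stage = "stratify"
            params = dict(cfg["stratify"] or {})
            gene = params.get("gene") or (
                results["robust_genes"][0] if results.get("robust_genes")
                else expression.index[0]
            )
            rule = params.get("rule", "median")
            assignment = dichotomize(expression.loc[gene], rule=rule)
            report = stratified_km(surv[0], surv[1], assignment)
            results["stratify"] = report
            write_report(
                outdir / "stratify.tsv", report.to_frame(), "stratify",
                {"gene": gene, "rule": rule, "seed": seed}, index=False,
            )

        if "methylation" in cfg and methylation is not None:
            stage = "methylation"
            params = dict(cfg["methylation"] or {})
            gene = params.get("gene", methylation["gene_id"].iloc[0])
            probes = methylation[methylation["gene_id"] == gene]
            expr_gene = expression.loc[gene]
            assignment = dichotomize(expr_gene, rule=params.get("rule", "median"))
            assoc = methylation_association(
                expr_gene, probes.drop(columns="gene_id"), assignment
            )
            results["methylation"] = assoc
            write_report(outdir / "methylation.tsv", assoc, "methylation",
                         {"gene": gene, "seed": seed})

        if cfg.get("summarize"):
            stage = "summarize"
            summary = cohort_summary(clinical)
            results["summary"] = summary
            write_report(outdir / "summary.tsv", summary.to_frame(), "summarize",
                         {"seed": seed}, index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return results
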