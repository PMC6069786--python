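"""Random-partition Cox screening of genes for association with survival.

A cohort of n patients is subsampled B times; the subset size of each draw
is uniform on an integer range (by default 50 up to the full cohort) and the
subset itself is a simple random sample without replacement. For every gene,
a univariate Cox proportional-hazards model of overall survival on
standardized expression is fitted within each subset, and the per-partition
coefficients and Wald p-values are aggregated (mean and median of both, plus
the fraction of partitions significant at alpha). A gene whose association
survives most partitions — i.e. most plausible sub-cohorts with differing
size and case mix — is a robustness-screened prognostic candidate, unlike a
gene that only reaches significance on the full cohort.

"Partition" here means repeated subsampling, not a disjoint split: the size
range extends to the full cohort, which a disjoint partition could not.
"""

from __future__ import annotations

import hashlib

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .survival import as_time_event, cox_fit, wald_summary

__all__ = [
    "draw_partitions",
    "PartitionCoxScreen",
    "partition_cox_screen",
    "genome_screen",
    "select_robust",
]


def _stable_hash(name: str) -> int:
    """Platform- and session-stable 64-bit hash of a gene identifier."""
    return int.from_bytes(hashlib.sha256(str(name).encode()).digest()[:8], "little")


def draw_partitions(n: int, b: int, min_size: int, max_size: int, rng) -> list:
    """Draw ``b`` random patient subsets with sizes uniform on [min_size, max_size].

    Each subset is sampled without replacement and returned with indices
    sorted ascending, so a subset equal to the full cohort reproduces the
    full-cohort computation exactly.
    """
    if b < 1:
        raise ValueError("number of partitions B must be >= 1")
    if not (2 <= min_size <= max_size):
        raise ValueError("need 2 <= min_size <= max_size")
    if max_size > n:
        raise ValueError(f"max_size {max_size} exceeds cohort size {n}")
    sizes = rng.integers(min_size, max_size + 1, size=b)
    return [np.sort(rng.choice(n, size=int(s), replace=False)) for s in sizes]


def _univariate_fit(x, time, event, ties, standardize):
    """One univariate Cox fit on (optionally standardized) expression.

    Returns (coef, se, p, converged); standardization uses the subset's own
    mean and SD so coefficients read as log-HR per 1 SD.
    """
    x = np.asarray(x, dtype=float)
    if standardize:
        sd = x.std()
        if sd == 0:
            return np.nan, np.nan, np.nan, False
        x = (x - x.mean()) / sd
    try:
        fit = cox_fit(x, time, event, ties=ties)
    except (ValueError, np.linalg.LinAlgError):
        return np.nan, np.nan, np.nan, False
    if not fit.converged:
        return float(fit.coef[0]), float(fit.se[0]), np.nan, False
    s = wald_summary(fit)
    return float(fit.coef[0]), float(fit.se[0]), float(s["p"].iloc[0]), True


class PartitionCoxScreen(BaseEstimator):
    """Screen genes for robust survival association via random partitions.

    Parameters
    ----------
    b : number of random partitions per gene (default 500).
    min_size, max_size : integer range of subset sizes; ``max_size=None``
        means the full cohort.
    alpha : two-sided significance threshold applied per partition (0.05).
    ties : tie correction passed to the Cox fits.
    standardize : standardize expression within each subset so coefficients
        are per 1 SD (default True).
    fraction_threshold, p_threshold : robustness selection rule used by
        :meth:`get_support` — fraction of significant partitions >=
        ``fraction_threshold`` and median partition p <= ``p_threshold``.
    random_state : master seed (int). ``None`` means 0: the screen is
        deterministic by construction. Per-gene RNG streams are derived from
        the master seed and a stable hash of the gene id, so results do not
        depend on gene order.
    keep_records : retain the per-partition (size, coef, p) records in
        ``records_``.

    Fitted attributes
    -----------------
    summary_ : DataFrame, one row per gene, sorted by full-cohort p
        ascending; columns include the full-cohort fit (``coef``, ``se``,
        ``hr``, ``p``, BH-adjusted ``q``), partition aggregates
        (``coef_mean``, ``coef_median``, ``p_mean``, ``p_median``,
        ``fraction_significant``) and ``n_nonconverged``.
    """

    def __init__(self, b=500, min_size=50, max_size=None, alpha=0.05,
                 ties="efron", standardize=True, fraction_threshold=0.9,
                 p_threshold=0.05, random_state=None, keep_records=False):
        self.b = b
        self.min_size = min_size
        self.max_size = max_size
        self.alpha = alpha
        self.ties = ties
        self.standardize = standardize
        self.fraction_threshold = fraction_threshold
        self.p_threshold = p_threshold
        self.random_state = random_state
        self.keep_records = keep_records

    def _master_seed(self) -> int:
        if self.random_state is None:
            return 0
        return int(self.random_state)

    def _screen_gene(self, name, x, time, event, n):
        max_size = n if self.max_size is None else self.max_size
        seed = np.random.SeedSequence([self._master_seed(), _stable_hash(name)])
        rng = np.random.default_rng(seed)
        parts = draw_partitions(n, self.b, self.min_size, max_size, rng)

        full_coef, full_se, full_p, full_ok = _univariate_fit(
            x, time, event, self.ties, self.standardize
        )
        rows = np.empty((self.b, 3))
        ok = np.zeros(self.b, dtype=bool)
        for i, idx in enumerate(parts):
            c, s, p, conv = _univariate_fit(
                x[idx], time[idx], event[idx], self.ties, self.standardize
            )
            rows[i] = (idx.size, c, p)
            ok[i] = conv
        if not ok.any():
            raise RuntimeError(f"all partition fits failed for gene {name}")
        coefs, pvals = rows[ok, 1], rows[ok, 2]

        def _mean(v):
            # identical values (degenerate size range) average to themselves
            # exactly instead of accumulating summation round-off
            return float(v[0]) if np.all(v == v[0]) else float(v.mean())

        rec = pd.DataFrame(rows, columns=["size", "coef", "p"]).assign(converged=ok) \
            if self.keep_records else None
        return {
            "gene": name,
            "coef": full_coef,
            "se": full_se,
            "hr": np.exp(full_coef),
            "p": full_p,
            "converged": full_ok,
            "b": self.b,
            "n_nonconverged": int((~ok).sum()),
            "coef_mean": _mean(coefs),
            "coef_median": float(np.median(coefs)),
            "p_mean": _mean(pvals),
            "p_median": float(np.median(pvals)),
            "fraction_significant": float(np.mean(pvals < self.alpha)),
        }, rec

    def fit(self, X, y):
        """Screen every gene (column of X, patients x genes) against survival y."""
        time, event = as_time_event(y)
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            Xa = X.to_numpy(dtype=float)
        else:
            Xa = np.asarray(X, dtype=float)
            if Xa.ndim == 1:
                Xa = Xa[:, None]
            names = [f"G{j + 1:04d}" for j in range(Xa.shape[1])]
        n = Xa.shape[0]
        if n != time.size:
            raise ValueError("expression rows must match number of patients")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")

        rows, records = [], {}
        for j, name in enumerate(names):
            row, rec = self._screen_gene(name, Xa[:, j], time, event, n)
            rows.append(row)
            if rec is not None:
                records[name] = rec
        summary = pd.DataFrame(rows).set_index("gene")
        finite = summary["p"].notna()
        q = np.full(len(summary), np.nan)
        if finite.any():
            q[finite.to_numpy()] = multipletests(
                summary.loc[finite, "p"], method="fdr_bh"
            )[1]
        summary["q"] = q
        self.summary_ = summary.sort_values("p", kind="stable")
        self.records_ = records
        self.n_features_in_ = Xa.shape[1]
        self.feature_names_in_ = np.asarray(names, dtype=object)
        return self

    def get_support(self, indices: bool = False):
        """Robust genes per the fraction/median-p selection rule, in input order."""
        selected = set(select_robust(
            self.summary_, self.fraction_threshold, self.p_threshold
        ))
        mask = np.array([g in selected for g in self.feature_names_in_])
        return np.where(mask)[0] if indices else mask


def partition_cox_screen(x, time, event=None, gene="gene", **params) -> pd.Series:
    """Partition-screen a single gene; returns its summary row as a Series."""
    if event is None:
        time, event = as_time_event(time)
    screen = PartitionCoxScreen(**params)
    x = np.asarray(x, dtype=float)
    screen.fit(pd.DataFrame({gene: x}), (time, event))
    return screen.summary_.loc[gene]


def genome_screen(expression: pd.DataFrame, clinical: pd.DataFrame, **params) -> pd.DataFrame:
    """Screen a genes x patients expression matrix against a clinical table.

    Patients are matched by id (intersection, clinical order); the ranked
    summary table (sorted by full-cohort p) is returned.
    """
    from .io import attach_event, join_cohort

    clinical = attach_event(clinical)
    clinical, expression, _ = join_cohort(clinical, expression)
    screen = PartitionCoxScreen(**params)
    screen.fit(
        expression.T,
        (clinical["os_months"].to_numpy(), clinical["event"].to_numpy()),
    )
    return screen.summary_


def select_robust(table: pd.DataFrame, fraction_threshold: float = 0.9,
                  p_threshold: float = 0.05) -> list:
    """Genes whose association survives the partition robustness rule.

    Keeps genes with fraction_significant >= fraction_threshold and median
    partition p <= p_threshold.
    """
    keep = (table["fraction_significant"] >= fraction_threshold) & (
        table["p_median"] <= p_threshold
    )
    return list(table.index[keep.fillna(False)])
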