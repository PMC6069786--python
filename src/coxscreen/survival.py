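"""Core survival statistics: Kaplan-Meier, log-rank, Cox proportional hazards.

These primitives are implemented from first principles (product-limit
estimator with Greenwood variance, Mantel-Haenszel log-rank with
hypergeometric moments, Newton-Raphson maximisation of the Cox partial
likelihood with Efron or Breslow tie handling) because the screening layer
needs full control over convergence reporting and tie conventions.

Conventions used throughout:

* time is in months and strictly positive; event is 1 for death, 0 for
  right-censoring at that time;
* a subject censored exactly at an event time is still at risk at that time;
* the Kaplan-Meier median is the smallest observed event time at which the
  estimated survival is <= 0.5, and is NaN when survival never reaches 0.5;
* Wald inference: CI = exp(coef +- z * SE), two-sided normal p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.linalg import LinAlgError
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "KMEstimate",
    "LogRankResult",
    "CoxFit",
    "KaplanMeier",
    "CoxPH",
    "make_survival",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "cox_score_test",
    "wald_summary",
]


# ---------------------------------------------------------------------------
# survival-outcome container helpers


def make_survival(time, event) -> np.ndarray:
    """Pack (time, event) into a structured array with fields 'time'/'event'.

    The structured form travels through sklearn pipelines as a single ``y``.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    y = np.empty(time.shape[0], dtype=[("event", "?"), ("time", "<f8")])
    y["time"] = time
    y["event"] = event.astype(bool)
    return y


def as_time_event(y) -> tuple[np.ndarray, np.ndarray]:
    """Coerce a survival outcome into validated (time, event) float arrays.

    Accepts a structured array with 'time'/'event' fields, a (time, event)
    tuple/list, an (n, 2) array with columns time then event, or a DataFrame
    with 'time'/'event' (or 'os_months'/'event') columns.
    """
    if isinstance(y, (tuple, list)) and len(y) == 2:
        time, event = y
    elif isinstance(y, pd.DataFrame):
        tcol = "time" if "time" in y.columns else "os_months"
        time, event = y[tcol], y["event"]
    elif hasattr(y, "dtype") and getattr(y.dtype, "names", None):
        time, event = y["time"], y["event"]
    else:
        arr = np.asarray(y, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError(
                "survival outcome must be (time, event), a structured array "
                "with 'time'/'event' fields, or an (n, 2) array"
            )
        time, event = arr[:, 0], arr[:, 1]
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    if time.shape != event.shape or time.ndim != 1:
        raise ValueError("time and event must be 1-d arrays of equal length")
    if time.size == 0:
        raise ValueError("empty survival data")
    if not np.all(np.isfinite(time)) or np.any(time <= 0):
        raise ValueError("survival times must be finite and > 0")
    if not np.all((event == 0) | (event == 1)):
        raise ValueError("event indicator must be 0 (censored) or 1 (death)")
    return time, event


# ---------------------------------------------------------------------------
# Kaplan-Meier


@dataclass
class KMEstimate:
    """Product-limit estimate over the distinct event times.

    ``survival[i]`` is S(t) just after ``times[i]``; ``se`` is the Greenwood
    standard error; ``median`` is NaN when survival never reaches 0.5.
    """

    times: np.ndarray
    survival: np.ndarray
    se: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    median: float
    n: int

    def survival_at(self, t) -> np.ndarray:
        """Step-function value of S at arbitrary times (S=1 before the first event)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if self.times.size == 0:
            return np.ones_like(t)
        idx = np.searchsorted(self.times, t, side="right") - 1
        return np.where(idx >= 0, self.survival[np.clip(idx, 0, None)], 1.0)


def km_estimate(time, event=None) -> KMEstimate:
    """Kaplan-Meier estimate with Greenwood standard errors and median."""
    if event is None:
        time, event = as_time_event(time)
    else:
        time, event = as_time_event((time, event))
    n = time.size
    # distinct event times; censored subjects only shrink later risk sets
    ut = np.unique(time[event == 1])
    if ut.size == 0:
        return KMEstimate(
            times=ut,
            survival=np.empty(0),
            se=np.empty(0),
            n_at_risk=np.empty(0, dtype=int),
            n_events=np.empty(0, dtype=int),
            median=float("nan"),
            n=n,
        )
    tsort = np.sort(time)
    at_risk = n - np.searchsorted(tsort, ut, side="left")
    etimes = np.sort(time[event == 1])
    d = np.searchsorted(etimes, ut, side="right") - np.searchsorted(etimes, ut, side="left")
    surv = np.cumprod(1.0 - d / at_risk)
    with np.errstate(divide="ignore", invalid="ignore"):
        gw = np.cumsum(np.where(at_risk > d, d / (at_risk * (at_risk - d)), np.inf))
        se = surv * np.sqrt(gw)
    se = np.where(surv == 0.0, 0.0, se)
    below = surv <= 0.5 + 1e-12
    median = float(ut[below][0]) if below.any() else float("nan")
    return KMEstimate(
        times=ut,
        survival=surv,
        se=se,
        n_at_risk=at_risk.astype(int),
        n_events=d.astype(int),
        median=median,
        n=n,
    )


class KaplanMeier(BaseEstimator):
    """Estimator wrapper around :func:`km_estimate`.

    Parameters are none; fitted attributes mirror :class:`KMEstimate` with
    trailing underscores. ``predict(times)`` evaluates the fitted survival
    step function.
    """

    def fit(self, y, X=None):
        est = km_estimate(y)
        self.estimate_ = est
        self.event_times_ = est.times
        self.survival_ = est.survival
        self.se_ = est.se
        self.at_risk_ = est.n_at_risk
        self.events_ = est.n_events
        self.median_ = est.median
        self.n_ = est.n
        return self

    def predict(self, times):
        return self.estimate_.survival_at(times)


# ---------------------------------------------------------------------------
# log-rank


@dataclass
class LogRankResult:
    statistic: float
    df: int
    pvalue: float
    observed: np.ndarray = field(default=None, repr=False)
    expected: np.ndarray = field(default=None, repr=False)
    groups: np.ndarray = field(default=None, repr=False)


def logrank_test(time, event, group) -> LogRankResult:
    """K-sample Mantel-Haenszel log-rank test.

    At each distinct event time the per-group death counts are compared with
    their hypergeometric expectations; the quadratic form uses the full
    covariance matrix with a generalized inverse, so the statistic is exactly
    invariant under relabeling of groups. Degrees of freedom = K - 1.
    """
    time, event = as_time_event((time, event))
    group = np.asarray(group)
    if group.shape != time.shape:
        raise ValueError("group labels must align with survival data")
    labels, gidx = np.unique(group, return_inverse=True)
    k = labels.size
    if k < 2:
        raise ValueError("log-rank test requires at least two non-empty groups")
    if event.sum() == 0:
        raise ValueError("log-rank test requires at least one event")

    ut = np.unique(time[event == 1])
    m = ut.size
    ng = np.zeros((m, k))
    dg = np.zeros((m, k))
    for g in range(k):
        tg = np.sort(time[gidx == g])
        ng[:, g] = tg.size - np.searchsorted(tg, ut, side="left")
        eg = np.sort(time[(gidx == g) & (event == 1)])
        dg[:, g] = np.searchsorted(eg, ut, side="right") - np.searchsorted(eg, ut, side="left")
    ntot = ng.sum(axis=1)
    dtot = dg.sum(axis=1)

    expected = dtot[:, None] * ng / ntot[:, None]
    observed = dg.sum(axis=0)
    u = observed - expected.sum(axis=0)

    # covariance: V_gh = sum_j d(n-d)/(n-1) * (delta n_g n - n_g n_h) / n^2
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(ntot > 1, dtot * (ntot - dtot) / (ntot - 1), 0.0)
    p = ng / ntot[:, None]
    V = np.einsum("j,jg,jh->gh", c, p, -p)
    V[np.diag_indices(k)] += np.einsum("j,jg->g", c, p)

    if not np.any(np.abs(V) > 0):
        raise ValueError("log-rank statistic undefined: zero total variance")
    stat = float(u @ np.linalg.pinv(V) @ u)
    stat = max(stat, 0.0)
    df = k - 1
    return LogRankResult(
        statistic=stat,
        df=df,
        pvalue=float(stats.chi2.sf(stat, df)),
        observed=observed,
        expected=expected.sum(axis=0),
        groups=labels,
    )


# ---------------------------------------------------------------------------
# Cox proportional hazards


class _PartialLikelihood:
    """Log partial likelihood, score and observed information.

    Subjects are sorted by time once; risk-set sums are reverse cumulative
    sums taken at the first index of each tied-time block, so censored
    subjects tied with an event time remain at risk there.
    """

    def __init__(self, X, time, event, ties):
        order = np.argsort(time, kind="stable")
        self.X = np.ascontiguousarray(X[order])
        self.t = time[order]
        self.e = event[order]
        _, self.first = np.unique(self.t, return_index=True)
        self.d = np.add.reduceat(self.e, self.first)
        self.mask = self.d > 0
        self.dd = self.d[self.mask]
        self.sum_x_events = np.add.reduceat(
            self.X * self.e[:, None], self.first, axis=0
        )[self.mask]
        self.max_d = int(self.dd.max()) if self.dd.size else 0
        self.ties = ties

    def __call__(self, beta):
        X, e, first, mask = self.X, self.e, self.first, self.mask
        eta = X @ beta
        eta = np.clip(eta, -500.0, 500.0)
        w = np.exp(eta)
        xw = X * w[:, None]
        xxw = np.einsum("ni,nj,n->nij", X, X, w)

        S0 = np.cumsum(w[::-1])[::-1]
        S1 = np.cumsum(xw[::-1], axis=0)[::-1]
        S2 = np.cumsum(xxw[::-1], axis=0)[::-1]
        idx = first[mask]
        R0, R1, R2 = S0[idx], S1[idx], S2[idx]
        dd = self.dd

        ll = float(np.sum(eta * e))
        p = X.shape[1]
        U = self.sum_x_events.sum(axis=0)
        I = np.zeros((p, p))

        if self.ties == "breslow":
            ll -= float(np.sum(dd * np.log(R0)))
            m = R1 / R0[:, None]
            U -= np.einsum("k,ki->i", dd, m)
            I += np.einsum("k,kij->ij", dd, R2 / R0[:, None, None])
            I -= np.einsum("k,ki,kj->ij", dd, m, m)
        else:  # efron
            ew = e * w
            D0 = np.add.reduceat(ew, first)[mask]
            D1 = np.add.reduceat(X * ew[:, None], first, axis=0)[mask]
            D2 = np.add.reduceat(np.einsum("ni,nj,n->nij", X, X, ew), first, axis=0)[mask]
            for l in range(self.max_d):
                sub = dd > l
                f = (l / dd[sub])[:, None]
                Z0 = R0[sub] - f[:, 0] * D0[sub]
                Z1 = R1[sub] - f * D1[sub]
                Z2 = R2[sub] - f[:, :, None] * D2[sub]
                ll -= float(np.sum(np.log(Z0)))
                m = Z1 / Z0[:, None]
                U -= m.sum(axis=0)
                I += np.einsum("kij->ij", Z2 / Z0[:, None, None])
                I -= np.einsum("ki,kj->ij", m, m)
        return ll, U, I


@dataclass
class CoxFit:
    """Result of one Cox proportional-hazards fit.

    ``coef`` are log hazard ratios; ``se`` comes from the inverse observed
    information at the optimum; ``hazard_ratio`` = exp(coef) exactly.
    """

    coef: np.ndarray
    se: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    ties: str
    names: list
    n: int
    n_events: int

    @property
    def hazard_ratio(self) -> np.ndarray:
        return np.exp(self.coef)

    def summary(self, level: float = 0.95) -> pd.DataFrame:
        return wald_summary(self, level=level)


def cox_fit(
    X,
    time,
    event=None,
    *,
    ties: str = "efron",
    max_iter: int = 50,
    tol: float = 1e-9,
    names=None,
) -> CoxFit:
    """Fit a Cox model by Newton-Raphson on the log partial likelihood.

    Convergence is declared when the largest score component falls below
    ``tol``; a coefficient walking past |beta| = 50 is flagged as divergence
    (monotone likelihood, e.g. perfect separation) and the fit is returned
    with ``converged=False`` rather than a silent answer.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown ties method: {ties!r}")
    if event is None:
        time, event = as_time_event(time)
    else:
        time, event = as_time_event((time, event))
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != time.size:
        raise ValueError("covariate matrix rows must match number of subjects")
    if not np.all(np.isfinite(X)):
        raise ValueError("covariates must be finite")
    if event.sum() < 1:
        raise ValueError("Cox fit requires at least one event")
    rng_ptp = X.max(axis=0) - X.min(axis=0)
    if np.any(rng_ptp == 0):
        j = int(np.argmax(rng_ptp == 0))
        label = names[j] if names is not None else f"column {j}"
        raise ValueError(f"constant covariate: {label}")

    pl = _PartialLikelihood(X, time, event, ties)
    p = X.shape[1]
    beta = np.zeros(p)
    ll, U, I = pl(beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if np.max(np.abs(U)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(I, U)
        except LinAlgError:
            break
        # step-halving keeps the likelihood monotone (concave objective)
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll_new, U_new, I_new = pl(cand)
            if ll_new >= ll - 1e-12:
                break
            factor /= 2.0
        beta, ll, U, I = cand, ll_new, U_new, I_new
        if np.max(np.abs(beta)) > 50.0:
            break
    else:
        it = max_iter
    if not converged and np.max(np.abs(U)) < tol and np.max(np.abs(beta)) <= 50.0:
        converged = True

    try:
        cov = np.linalg.inv(I)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except LinAlgError:
        se = np.full(p, np.nan)
        converged = False
    # a flat likelihood (e.g. perfect separation) stalls the score below tol
    # while the coefficient and its SE are astronomically large; flag it
    if converged and (np.max(np.abs(beta)) > 50.0 or np.nanmax(se) > 50.0):
        converged = False
    if names is None:
        names = [f"x{j}" for j in range(p)]
    return CoxFit(
        coef=beta,
        se=se,
        loglik=ll,
        n_iter=it,
        converged=converged,
        ties=ties,
        names=list(names),
        n=time.size,
        n_events=int(event.sum()),
    )


def wald_summary(fit: CoxFit, level: float = 0.95) -> pd.DataFrame:
    """Per-covariate hazard ratios with Wald confidence intervals and p-values."""
    if not fit.converged:
        raise ValueError("Wald summary requested for a non-converged Cox fit")
    if not 0.0 < level < 1.0:
        raise ValueError("confidence level must be in (0, 1)")
    z = stats.norm.ppf(0.5 + level / 2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        zstat = np.where(fit.se > 0, fit.coef / fit.se, np.inf * np.sign(fit.coef))
    pvals = 2.0 * stats.norm.sf(np.abs(zstat))
    pvals = np.where(fit.coef == 0.0, 1.0, pvals)
    return pd.DataFrame(
        {
            "coef": fit.coef,
            "se": fit.se,
            "hr": np.exp(fit.coef),
            "ci_low": np.exp(fit.coef - z * fit.se),
            "ci_high": np.exp(fit.coef + z * fit.se),
            "p": pvals,
        },
        index=pd.Index(fit.names, name="covariate"),
    )


def cox_score_test(X, time, event=None, *, ties: str = "breslow"):
    """Score (Rao) test of beta = 0 for the Cox model.

    For a single binary covariate with no tied event times this equals the
    two-sample log-rank chi-square.
    """
    if event is None:
        time, event = as_time_event(time)
    else:
        time, event = as_time_event((time, event))
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    pl = _PartialLikelihood(X, time, event, ties)
    _, U, I = pl(np.zeros(X.shape[1]))
    stat = float(U @ np.linalg.solve(I, U))
    return stat, float(stats.chi2.sf(stat, X.shape[1]))


class CoxPH(BaseEstimator):
    """Cox proportional-hazards regression in sklearn estimator form.

    Parameters
    ----------
    ties : {"efron", "breslow"}
        Tie correction for the partial likelihood. Efron is the default;
        the two are identical when no event times are tied.
    max_iter, tol : Newton-Raphson controls; convergence is max |score| < tol.

    Fitted attributes: ``coef_``, ``se_``, ``hazard_ratios_``, ``loglik_``,
    ``n_iter_``, ``converged_``, ``feature_names_in_`` (when X is a
    DataFrame), ``fit_result_`` (the underlying :class:`CoxFit`).
    """

    def __init__(self, ties: str = "efron", max_iter: int = 50, tol: float = 1e-9):
        self.ties = ties
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y):
        names = list(X.columns) if isinstance(X, pd.DataFrame) else None
        Xa = np.asarray(X, dtype=float)
        if Xa.ndim == 1:
            Xa = Xa[:, None]
        time, event = as_time_event(y)
        res = cox_fit(
            Xa, time, event,
            ties=self.ties, max_iter=self.max_iter, tol=self.tol, names=names,
        )
        self.fit_result_ = res
        self.coef_ = res.coef
        self.se_ = res.se
        self.hazard_ratios_ = res.hazard_ratio
        self.loglik_ = res.loglik
        self.n_iter_ = res.n_iter
        self.converged_ = res.converged
        self.n_features_in_ = Xa.shape[1]
        if names is not None:
            self.feature_names_in_ = np.asarray(names, dtype=object)
        return self

    def predict(self, X):
        """Linear predictor (log relative hazard) for each subject."""
        Xa = np.asarray(X, dtype=float)
        if Xa.ndim == 1:
            Xa = Xa[:, None]
        return Xa @ self.coef_

    def summary(self, level: float = 0.95) -> pd.DataFrame:
        return wald_summary(self.fit_result_, level=level)
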