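"""Missing-data handling: chained-equation multiple imputation and
median-imputation-by-outcome.

Two devices are provided, mirroring how the analysis uses them:

* :func:`mice_impute` — multiple imputation by chained equations.  Each
  incomplete variable is visited in a fixed order each iteration;
  continuous variables are imputed by predictive mean matching (donor pool
  k=5) against an OLS fit, binary variables by draws from a logistic fit.
  The result is a stack of ``m`` completed datasets analysed separately
  and pooled by Rubin's rules (:func:`pool_estimates`).
* :func:`median_impute_by_outcome` — single imputation of each missing
  cell with its outcome-group median (continuous) or mode (binary, ties
  to 0).  Used upstream of penalised model updating so that variable
  selection is not fragmented across imputed datasets.

AUCs should be pooled on the logit scale (:func:`pool_auc`) since pooling
raw AUCs can leave the unit interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.linear_model import LogisticRegression

__all__ = [
    "ImputedStack",
    "mice_impute",
    "median_impute_by_outcome",
    "pool_estimates",
    "pool_auc",
    "PooledEstimate",
]


@dataclass
class ImputedStack:
    """m completed copies of a cohort plus provenance."""

    datasets: list[pd.DataFrame]
    method: str
    iterations: int
    seed: int
    imputation_model_vars: list[str]
    convergence_traces: dict = field(default_factory=dict)

    @property
    def m(self) -> int:
        return len(self.datasets)

    def __post_init__(self) -> None:
        if self.method not in ("mice", "median_by_outcome"):
            raise ValueError(f"unknown imputation method {self.method!r}")
        if self.method == "median_by_outcome" and self.m != 1:
            raise ValueError("median_by_outcome produces exactly one dataset")


def _is_binary(col: pd.Series) -> bool:
    vals = col.dropna().unique()
    return len(vals) > 0 and set(np.unique(vals)).issubset({0.0, 1.0, 0, 1, False, True})


def _ols_predict(X: np.ndarray, y: np.ndarray, Xnew: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    Xd = np.column_stack([np.ones(len(X)), X])
    beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
    fitted = Xd @ beta
    pred = np.column_stack([np.ones(len(Xnew)), Xnew]) @ beta
    return fitted, pred


def _pmm_draw(
    rng: np.random.Generator,
    fitted_obs: np.ndarray,
    y_obs: np.ndarray,
    pred_mis: np.ndarray,
    k: int = 5,
) -> np.ndarray:
    """Predictive mean matching: for each missing cell, draw one donor at
    random among the k observed cases with closest fitted value."""
    k = min(k, len(y_obs))
    order = np.argsort(fitted_obs, kind="stable")
    fitted_sorted = fitted_obs[order]
    y_sorted = y_obs[order]
    pos = np.searchsorted(fitted_sorted, pred_mis)
    out = np.empty(len(pred_mis))
    for i, p in enumerate(pos):
        lo = max(0, min(p - k, len(y_sorted) - k))
        window = slice(lo, lo + 2 * k)
        cand_f = fitted_sorted[window]
        cand_y = y_sorted[window]
        nearest = np.argsort(np.abs(cand_f - pred_mis[i]), kind="stable")[:k]
        out[i] = cand_y[nearest[rng.integers(len(nearest))]]
    return out


def mice_impute(
    cohort: pd.DataFrame,
    variables: Sequence[str],
    m: int = 100,
    iterations: int = 10,
    seed: int = 0,
    outcome: str = "oxygen_outcome",
    extra_predictors: Sequence[str] = ("age_months",),
    pmm_k: int = 5,
) -> ImputedStack:
    """Multiple imputation by chained equations.

    ``variables`` are the columns to complete; the imputation model for
    each uses all other ``variables`` (current completed values), the
    outcome, and ``extra_predictors`` (all must be fully observed).
    Continuous variables use predictive mean matching with a donor pool of
    ``pmm_k``; binary variables use logistic draws.  Observed cells are
    never altered.  Deterministic for a fixed seed.
    """
    for v in variables:
        if cohort[v].notna().sum() == 0:
            raise ValueError(f"variable {v!r} has zero observed values; cannot impute")
    for v in (outcome, *extra_predictors):
        if cohort[v].isna().any():
            raise ValueError(f"{v!r} must be fully observed to enter every imputation model")

    variables = list(variables)
    model_vars = variables + [outcome, *extra_predictors]
    base = cohort.copy()
    miss_mask = {v: base[v].isna().to_numpy() for v in variables}
    binary = {v: _is_binary(base[v]) for v in variables}
    rng = np.random.default_rng(seed)

    datasets: list[pd.DataFrame] = []
    traces: dict[str, list[list[float]]] = {v: [] for v in variables}
    for _ in range(m):
        work = base.copy()
        # initialise each missing cell with a random observed value
        for v in variables:
            mask = miss_mask[v]
            if mask.any():
                obs = work.loc[~mask, v].to_numpy(dtype=float)
                work.loc[mask, v] = rng.choice(obs, size=mask.sum(), replace=True)
        trace_run = {v: [] for v in variables}
        for _it in range(iterations):
            for v in variables:
                mask = miss_mask[v]
                if not mask.any():
                    continue
                predictors = [c for c in model_vars if c != v]
                X = work[predictors].to_numpy(dtype=float)
                y = work[v].to_numpy(dtype=float)
                X_obs, y_obs = X[~mask], y[~mask]
                X_mis = X[mask]
                if binary[v]:
                    if len(np.unique(y_obs)) < 2:
                        work.loc[mask, v] = float(y_obs[0])
                    else:
                        clf = LogisticRegression(max_iter=200, C=1.0)
                        clf.fit(X_obs, y_obs)
                        p = clf.predict_proba(X_mis)[:, 1]
                        work.loc[mask, v] = (rng.random(len(p)) < p).astype(float)
                else:
                    fitted_obs, pred_mis = _ols_predict(X_obs, y_obs, X_mis)
                    work.loc[mask, v] = _pmm_draw(rng, fitted_obs, y_obs, pred_mis, k=pmm_k)
                trace_run[v].append(float(work[v].mean()))
        for v in variables:
            traces[v].append(trace_run[v])
        datasets.append(work)

    return ImputedStack(
        datasets=datasets,
        method="mice",
        iterations=iterations,
        seed=seed,
        imputation_model_vars=model_vars,
        convergence_traces=traces,
    )


def median_impute_by_outcome(
    cohort: pd.DataFrame,
    variables: Sequence[str],
    outcome: str = "oxygen_outcome",
) -> pd.DataFrame:
    """Single imputation with outcome-group medians (continuous) or modes
    (binary; an exact tie imputes 0).

    Both outcome groups must contain at least one observed value for each
    variable.
    """
    groups = cohort[outcome].dropna().unique()
    if len(groups) < 2:
        raise ValueError("both outcome groups must be present")
    out = cohort.copy()
    for v in variables:
        col = out[v].astype(float)
        if not col.isna().any():
            continue
        binary = _is_binary(col)
        for g in (0, 1):
            gmask = (out[outcome] == g).to_numpy()
            observed = col[gmask & col.notna().to_numpy()]
            if observed.empty:
                raise ValueError(
                    f"outcome group {g} has no observed values for {v!r}"
                )
            if binary:
                frac1 = float(observed.mean())
                fill = 1.0 if frac1 > 0.5 else 0.0  # tie -> 0
            else:
                fill = float(observed.median())
            fmask = gmask & col.isna().to_numpy()
            col[fmask] = fill
        out[v] = col
    return out


@dataclass
class PooledEstimate:
    """Rubin's-rules summary of an estimate over m imputed datasets."""

    estimate: float
    total_variance: float
    within_variance: float
    between_variance: float
    ci_lower: float
    ci_upper: float
    m: int

    @property
    def se(self) -> float:
        return float(np.sqrt(self.total_variance))


def pool_estimates(
    estimates: Sequence[float],
    variances: Sequence[float],
    alpha: float = 0.05,
) -> PooledEstimate:
    """Pool per-dataset estimates by Rubin's rules.

    Pooled point estimate = mean; total variance = mean within-imputation
    variance + (1 + 1/m) x between-imputation variance.  The confidence
    interval uses a normal approximation (for m = 1 the between term is 0
    and the result reduces to the single-dataset estimate).
    """
    est = np.asarray(estimates, dtype=float)
    var = np.asarray(variances, dtype=float)
    if est.size == 0:
        raise ValueError("need at least one estimate to pool")
    if est.shape != var.shape:
        raise ValueError("estimates and variances must have the same length")
    m = est.size
    pooled = float(est.mean())
    within = float(var.mean())
    between = float(est.var(ddof=1)) if m > 1 else 0.0
    total = within + (1 + 1 / m) * between
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(total)
    return PooledEstimate(
        estimate=pooled,
        total_variance=total,
        within_variance=within,
        between_variance=between,
        ci_lower=pooled - half,
        ci_upper=pooled + half,
        m=m,
    )


def pool_auc(
    aucs: Sequence[float],
    variances: Sequence[float] | None = None,
    alpha: float = 0.05,
) -> PooledEstimate:
    """Pool AUCs on the logit scale and back-transform.

    Raw-scale pooling can produce intervals outside [0, 1]; the logit
    transform keeps the pooled AUC and its CI inside the unit interval.
    Variances, when given, are mapped by the delta method.
    """
    a = np.clip(np.asarray(aucs, dtype=float), 1e-9, 1 - 1e-9)
    logit_a = special.logit(a)
    if variances is None:
        var_logit = np.zeros_like(a)
    else:
        v = np.asarray(variances, dtype=float)
        var_logit = v / (a * (1 - a)) ** 2  # d logit / d a = 1/(a(1-a))
    pooled = pool_estimates(logit_a, var_logit, alpha=alpha)
    return PooledEstimate(
        estimate=float(special.expit(pooled.estimate)),
        total_variance=pooled.total_variance,
        within_variance=pooled.within_variance,
        between_variance=pooled.between_variance,
        ci_lower=float(special.expit(pooled.ci_lower)),
        ci_upper=float(special.expit(pooled.ci_upper)),
        m=pooled.m,
    )
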