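"""Discrimination, calibration and cut-off classification metrics.

The validation surface for both points-based scores and fitted risk
models:

* :func:`auc` — area under the ROC curve (concordance probability, ties
  counted one half) with a DeLong 95% CI.
* :func:`calibration` — calibration slope and intercept from a logistic
  refit of the outcome on the logit of predicted risk, plus decile-binned
  observed-vs-expected points with exact (Clopper-Pearson) binomial CIs
  for plotting.
* :func:`classify_at_cutoffs` — one classification row per cut-off with
  sensitivity, specificity, predictive values, likelihood ratios, referral
  workload columns and the empirical number needed to refer.  Proportion
  CIs use the Wilson method; likelihood-ratio CIs use the log method.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import special, stats
import statsmodels.api as sm
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "auc",
    "roc_auc",
    "delong_variance",
    "calibration",
    "CalibrationResult",
    "calibration_slope",
    "classify_at_cutoffs",
    "ClassificationRow",
    "prevalence_percent",
]


def prevalence_percent(outcome) -> float:
    """Outcome prevalence as a percentage (events / n x 100)."""
    y = np.asarray(outcome, dtype=float)
    if y.size == 0:
        raise ValueError("empty outcome vector")
    return float(100.0 * y.mean())


# ---------------------------------------------------------------------------
# discrimination


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def roc_auc(risk, outcome) -> float:
    """Concordance-probability AUC with ties counted one half
    (midrank / Mann-Whitney formulation)."""
    y = np.asarray(outcome, dtype=float)
    r = np.asarray(risk, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both outcome classes must be present")
    ranks = _midranks(r)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def delong_variance(risk, outcome) -> float:
    """DeLong variance of the empirical AUC (placement-value form)."""
    y = np.asarray(outcome, dtype=float)
    r = np.asarray(risk, dtype=float)
    pos = r[y == 1]
    neg = r[y == 0]
    m, n = len(pos), len(neg)
    all_ranks = _midranks(np.concatenate([pos, neg]))
    pos_ranks = _midranks(pos)
    neg_ranks = _midranks(neg)
    # placement values V10 (per positive) and V01 (per negative)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(s10 / m + s01 / n)


def auc(risk, outcome, alpha: float = 0.05) -> tuple[float, tuple[float, float], float]:
    """AUC with a DeLong confidence interval.

    Returns ``(auc, (lower, upper), variance)``; the interval is clipped
    to [0, 1].
    """
    a = roc_auc(risk, outcome)
    var = delong_variance(risk, outcome)
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(var)
    return a, (max(0.0, a - half), min(1.0, a + half)), var


# ---------------------------------------------------------------------------
# calibration


@dataclass
class CalibrationResult:
    slope: float
    intercept: float
    bins: pd.DataFrame  # bin mid-risk, observed proportion, exact CI, n
    rug_positive: np.ndarray
    rug_negative: np.ndarray


def calibration_slope(risk, outcome) -> float:
    """Slope from a logistic refit of the outcome on logit(risk)."""
    return calibration(risk, outcome).slope


def calibration(risk, outcome, bins: int = 10) -> CalibrationResult:
    """Calibration slope/intercept plus binned observed-vs-expected data.

    Risks of exactly 0 or 1 are clipped to [1e-6, 1-1e-6] with a warning.
    A constant risk vector has no defined slope and raises ``ValueError``.
    """
    r = np.asarray(risk, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if ((r <= 0) | (r >= 1)).any():
        import warnings

        warnings.warn("risks at 0 or 1 clipped to [1e-6, 1 - 1e-6]", stacklevel=2)
        r = np.clip(r, 1e-6, 1 - 1e-6)
    lp = special.logit(r)
    if np.ptp(lp) < 1e-12:
        raise ValueError("constant predicted risk: calibration slope undefined")
    X = sm.add_constant(lp)
    fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    slope = float(fit.params[1])
    intercept = float(fit.params[0])

    edges = np.quantile(r, np.linspace(0, 1, bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    idx = np.digitize(r, edges[1:-1])
    rows = []
    for b in range(bins):
        mask = idx == b
        nb = int(mask.sum())
        if nb == 0:
            continue
        k = int(y[mask].sum())
        lo, hi = proportion_confint(k, nb, method="beta")  # exact binomial
        rows.append(
            {
                "bin": b,
                "n": nb,
                "mean_predicted": float(r[mask].mean()),
                "observed": k / nb,
                "ci_lower": float(lo),
                "ci_upper": float(hi),
            }
        )
    return CalibrationResult(
        slope=slope,
        intercept=intercept,
        bins=pd.DataFrame(rows),
        rug_positive=np.sort(r[y == 1]),
        rug_negative=np.sort(r[y == 0]),
    )


# ---------------------------------------------------------------------------
# classification tables


@dataclass
class ClassificationRow:
    """One cut-off's confusion counts and derived triage metrics.

    ``cases_referred_pct`` and companions describe referral workload;
    ``ratio_incorrect_to_correct_referrals`` is FP:TP, and
    ``ratio_correct_to_incorrect_community`` is TN:FN (infinite when no
    event is missed).  ``nnr_empirical`` is the number referred per true
    case identified, (TP+FP)/TP = 1/PPV.
    """

    rule: float
    n: int
    TP: int
    FP: int
    TN: int
    FN: int
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    npv: float
    npv_ci: tuple[float, float]
    ppv: float
    ppv_ci: tuple[float, float]
    lr_pos: float
    lr_pos_ci: tuple[float, float]
    lr_neg: float
    lr_neg_ci: tuple[float, float]
    cases_referred: int
    cases_referred_pct: float
    cases_community: int
    cases_community_pct: float
    ratio_incorrect_to_correct_referrals: float
    ratio_correct_to_incorrect_community: float
    nnr_empirical: float

    def as_dict(self) -> dict:
        return asdict(self)


def _wilson(k: int, n: int) -> tuple[float, float]:
    if n == 0:
        return (float("nan"), float("nan"))
    lo, hi = proportion_confint(k, n, method="wilson")
    return (float(lo), float(hi))


def _lr_ci(lr: float, se_log: float) -> tuple[float, float]:
    if not np.isfinite(lr) or lr <= 0 or not np.isfinite(se_log):
        return (float("nan"), float("nan"))
    z = stats.norm.ppf(0.975)
    return (float(lr * np.exp(-z * se_log)), float(lr * np.exp(z * se_log)))


def _one_row(pred_pos: np.ndarray, y: np.ndarray, rule: float) -> ClassificationRow:
    tp = int(((pred_pos == 1) & (y == 1)).sum())
    fp = int(((pred_pos == 1) & (y == 0)).sum())
    tn = int(((pred_pos == 0) & (y == 0)).sum())
    fn = int(((pred_pos == 0) & (y == 1)).sum())
    n = tp + fp + tn + fn
    pos, neg = tp + fn, fp + tn
    sens = tp / pos if pos else float("nan")
    spec = tn / neg if neg else float("nan")
    ppv = tp / (tp + fp) if tp + fp else float("nan")
    npv = tn / (tn + fn) if tn + fn else float("nan")
    lr_pos = sens / (1 - spec) if spec < 1 else float("inf")
    lr_neg = (1 - sens) / spec if spec > 0 else float("inf")
    # log-method standard errors for likelihood ratios
    with np.errstate(divide="ignore", invalid="ignore"):
        se_lrp = (
            np.sqrt(1 / tp - 1 / pos + 1 / fp - 1 / neg)
            if tp > 0 and fp > 0
            else float("nan")
        )
        se_lrn = (
            np.sqrt(1 / fn - 1 / pos + 1 / tn - 1 / neg)
            if fn > 0 and tn > 0
            else float("nan")
        )
    referred = tp + fp
    community = tn + fn
    return ClassificationRow(
        rule=float(rule),
        n=n,
        TP=tp,
        FP=fp,
        TN=tn,
        FN=fn,
        sensitivity=sens,
        sensitivity_ci=_wilson(tp, pos),
        specificity=spec,
        specificity_ci=_wilson(tn, neg),
        npv=npv,
        npv_ci=_wilson(tn, tn + fn),
        ppv=ppv,
        ppv_ci=_wilson(tp, tp + fp),
        lr_pos=lr_pos,
        lr_pos_ci=_lr_ci(lr_pos, se_lrp),
        lr_neg=lr_neg,
        lr_neg_ci=_lr_ci(lr_neg, se_lrn),
        cases_referred=referred,
        cases_referred_pct=100.0 * referred / n if n else float("nan"),
        cases_community=community,
        cases_community_pct=100.0 * community / n if n else float("nan"),
        ratio_incorrect_to_correct_referrals=fp / tp if tp else float("inf"),
        ratio_correct_to_incorrect_community=tn / fn if fn else float("inf"),
        nnr_empirical=referred / tp if tp else float("inf"),
    )


def classify_at_cutoffs(values, outcome, cutoffs) -> pd.DataFrame:
    """Classification table: one row per cut-off, referral when
    ``value >= cutoff`` (both for integer score cut-offs and probability
    thresholds).

    ``values`` may be score points or predicted probabilities; rows with a
    missing value or outcome are dropped first (full-case behaviour — pass
    imputed data to avoid it).
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(outcome, dtype=float)
    keep = ~(np.isnan(v) | np.isnan(y))
    v, y = v[keep], y[keep]
    rows = [_one_row((v >= c).astype(int), y, c) for c in sorted(set(np.asarray(cutoffs, dtype=float)))]
    df = pd.DataFrame([r.as_dict() for r in rows])
    df.attrs["analysed_n"] = int(len(v))
    df.attrs["analysed_events"] = int(y.sum())
    return df
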