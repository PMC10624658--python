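"""End-to-end analysis pipeline.

Orchestrates: simulate (or load) a cohort -> apply scenario filters ->
descriptive summary -> points-based score validation (classification
tables, AUC) -> chained-equation imputation -> score-component risk models
with bootstrap optimism correction -> lasso-updated models -> probability-
threshold classification tables -> decision curves -> machine-readable
report.

Three sensitivity scenarios mirror the study's robustness checks and are
independent, composable flags:

* ``exclude_baseline_hypoxaemia`` — drop presentations with observed
  SpO2 < 90% at presentation (settings with universal pulse oximetry);
* ``one_visit_per_child`` — keep one random presentation per child
  (clustering check in lieu of random effects);
* ``reclassify_community_oxygen`` — conservatively flip a stated number
  (or explicit list) of community-managed, outcome-negative presentations
  to outcome-positive (late-oxygen follow-up check).
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__ as _pkg_version
from .cohort_synth import (
    CANDIDATE_PREDICTORS,
    CohortSpec,
    generate_cohort,
    missingness_summary,
    read_cohort,
)
from .decision_analysis import decision_curve, default_threshold_grid
from .evaluation import auc as auc_ci
from .evaluation import calibration, classify_at_cutoffs, prevalence_percent
from .imputation import median_impute_by_outcome, mice_impute, pool_auc
from .modeling import (
    ModelSpec,
    bootstrap_optimism,
    fit_logistic,
    knot_locations,
    lasso_update,
)
from .scores import SCORE_NAMES, ThresholdTable, score_table

log = logging.getLogger("ari_triage.pipeline")

__all__ = ["AnalysisConfig", "run_pipeline", "cohort_summary", "apply_scenarios"]

_CONTINUOUS_SUMMARY = (
    "age_months",
    "heart_rate",
    "resp_rate",
    "temp_axillary",
    "spo2",
    "waz",
)
_BINARY_SUMMARY = ("crt_prolonged", "avpu_not_alert", "resp_distress", "admitted")


@dataclass
class AnalysisConfig:
    """Configuration of one pipeline run.

    The default ``demo`` profile (m=20 imputations, B=20 bootstraps) keeps
    a full run to a few minutes on one CPU; the study-scale settings are
    m=100, B=100.
    """

    seed: int = 1
    cohort_csv: str | None = None  # None -> simulate
    n_children: int = 756
    m_imputations: int = 20
    n_bootstrap: int = 20
    scores: tuple[str, ...] = SCORE_NAMES
    score_cutoffs: tuple[int, ...] = (1, 2, 3)
    prob_thresholds: tuple[float, ...] = (0.01, 0.05, 0.10, 0.20, 0.40)
    dca_grid: tuple[float, float, float] = (0.01, 0.40, 0.005)
    mice_iterations: int = 5
    exclude_baseline_hypoxaemia: bool = False
    one_visit_per_child: bool = False
    reclassify_community_oxygen: int | list | None = None
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        d = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


# ---------------------------------------------------------------------------
# scenario filters


def apply_scenarios(df: pd.DataFrame, config: AnalysisConfig) -> pd.DataFrame:
    """Apply the configured sensitivity-scenario filters, in a fixed order
    (reclassify, then one-visit, then hypoxaemia exclusion)."""
    rng = np.random.default_rng(config.seed + 7919)
    out = df.copy()

    if config.reclassify_community_oxygen is not None:
        sel = config.reclassify_community_oxygen
        community = (out["admitted"] == 0) & (out["oxygen_outcome"] == 0)
        if isinstance(sel, int):
            candidates = out.index[community].to_numpy()
            k = min(sel, len(candidates))
            flip = rng.choice(candidates, size=k, replace=False)
        else:
            flip = out.index[community & out["visit_id"].isin(sel)]
        out.loc[flip, "oxygen_outcome"] = 1
        log.info("scenario reclassify_community_oxygen: flipped %d records", len(flip))

    if config.one_visit_per_child:
        pick = (
            out.groupby("child_id", sort=True)
            .apply(lambda g: g.index[rng.integers(len(g))], include_groups=False)
            .to_numpy()
        )
        out = out.loc[np.sort(pick)]
        log.info("scenario one_visit_per_child: %d records kept", len(out))

    if config.exclude_baseline_hypoxaemia:
        hypox = out["spo2"].notna() & (out["spo2"] < 90)
        out = out.loc[~hypox]
        log.info("scenario exclude_baseline_hypoxaemia: dropped %d records", int(hypox.sum()))

    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# descriptive summary


def _continuous_p(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(np.concatenate([a, b])) < 1e-12:
        return 1.0
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def _binary_p(a: np.ndarray, b: np.ndarray) -> tuple[float, str]:
    k = np.array(
        [
            [int((a == 0).sum()), int((a == 1).sum())],
            [int((b == 0).sum()), int((b == 1).sum())],
        ]
    )
    if (k.sum(axis=0) == 0).any():
        return 1.0, "constant"
    expected = np.outer(k.sum(axis=1), k.sum(axis=0)) / k.sum()
    if (expected < 5).any():  # small-count rule -> exact test
        return float(stats.fisher_exact(k)[1]), "fisher"
    return float(stats.chi2_contingency(k, correction=False)[1]), "chi2"


def cohort_summary(records: pd.DataFrame, outcome: str = "oxygen_outcome") -> pd.DataFrame:
    """Outcome-stratified descriptive table.

    Continuous variables: median (IQR), Wilcoxon rank-sum p.  Binary
    variables: n/N (%), chi-squared p, or Fisher's exact when any expected
    cell count is below 5.  Raises if either outcome stratum is empty.
    """
    y = records[outcome]
    if y.isna().any():
        raise ValueError("outcome must be fully observed")
    g0, g1 = records[y == 0], records[y == 1]
    if len(g0) == 0 or len(g1) == 0:
        raise ValueError("both outcome strata must be non-empty")

    def med_iqr(s: pd.Series) -> str:
        s = s.dropna()
        if s.empty:
            return "-"
        return f"{s.median():.1f} ({s.quantile(0.25):.1f}, {s.quantile(0.75):.1f})"

    def n_pct(s: pd.Series) -> str:
        s = s.dropna()
        if s.empty:
            return "-"
        return f"{int(s.sum())}/{len(s)} ({100 * s.mean():.1f}%)"

    rows = []
    for v in _CONTINUOUS_SUMMARY:
        if v not in records.columns:
            continue
        a, b = g0[v].dropna().to_numpy(), g1[v].dropna().to_numpy()
        rows.append(
            {
                "variable": v,
                "type": "continuous",
                "overall": med_iqr(records[v]),
                "outcome_negative": med_iqr(g0[v]),
                "outcome_positive": med_iqr(g1[v]),
                "p_value": _continuous_p(a, b) if len(a) and len(b) else float("nan"),
                "test": "ranksum",
            }
        )
    for v in _BINARY_SUMMARY:
        if v not in records.columns:
            continue
        a, b = g0[v].dropna().to_numpy(), g1[v].dropna().to_numpy()
        p, test = _binary_p(a, b) if len(a) and len(b) else (float("nan"), "none")
        rows.append(
            {
                "variable": v,
                "type": "binary",
                "overall": n_pct(records[v]),
                "outcome_negative": n_pct(g0[v]),
                "outcome_positive": n_pct(g1[v]),
                "p_value": p,
                "test": test,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pipeline


def _stage(name: str, n_in: int, n_out: int) -> None:
    log.info("stage=%s n_in=%d n_out=%d", name, n_in, n_out)


def run_pipeline(config: AnalysisConfig) -> dict:
    """Run the full analysis; returns a JSON-serialisable report bundle.

    When ``config.out_dir`` is set, also writes: the cohort summary,
    per-score classification tables, per-model probability-threshold
    tables, fitted models as JSON, decision-curve data as CSV and the full
    ``report.json``.  Identical config + seed give an identical report.
    """
    if not log.handlers:
        logging.basicConfig(stream=sys.stderr, level=logging.INFO)

    # -- cohort ----------------------------------------------------------
    if config.cohort_csv:
        cohort = read_cohort(config.cohort_csv)
    else:
        cohort = generate_cohort(CohortSpec(n_children=config.n_children, seed=config.seed))
    n0 = len(cohort)
    cohort = apply_scenarios(cohort, config)
    _stage("scenarios", n0, len(cohort))
    if cohort["oxygen_outcome"].sum() < 10:
        raise RuntimeError(
            f"stage=scenarios: only {int(cohort['oxygen_outcome'].sum())} events "
            f"remain among {len(cohort)} records; cannot model"
        )

    y_all = cohort["oxygen_outcome"].to_numpy(dtype=float)
    report: dict = {
        "provenance": {
            "package_version": _pkg_version,
            "config": config.to_dict(),
            "config_digest": config.digest(),
            "seed": config.seed,
        },
        "cohort": {
            "n_presentations": int(len(cohort)),
            "n_children": int(cohort["child_id"].nunique()),
            "events": int(y_all.sum()),
            "prevalence_pct": prevalence_percent(y_all),
            "missingness": missingness_summary(cohort).round(4).to_dict(),
        },
    }

    summary = cohort_summary(cohort)
    report["cohort_summary"] = summary.to_dict(orient="records")

    # -- points-based scores (full-case) ---------------------------------
    thresholds = ThresholdTable.default()
    scored = score_table(cohort, thresholds)
    report["provenance"]["threshold_table_version"] = thresholds.version
    report["scores"] = {}
    for s in config.scores:
        complete = scored[f"{s}_complete"]
        pts = scored.loc[complete, s]
        y_s = cohort.loc[complete, "oxygen_outcome"]
        table3 = classify_at_cutoffs(pts, y_s, config.score_cutoffs)
        a, ci, _ = auc_ci(pts, y_s)
        report["scores"][s] = {
            "full_case_n": int(complete.sum()),
            "full_case_events": int(y_s.sum()),
            "auc": a,
            "auc_ci": list(ci),
            "classification": table3.to_dict(orient="records"),
        }
    _stage("scores", len(cohort), len(cohort))

    # -- imputation ------------------------------------------------------
    impute_vars = [v for v in CANDIDATE_PREDICTORS if cohort[v].isna().any()]
    if impute_vars:
        stack = mice_impute(
            cohort,
            impute_vars,
            m=config.m_imputations,
            iterations=config.mice_iterations,
            seed=config.seed + 11,
        )
        datasets = stack.datasets
    else:
        datasets = [cohort]
    _stage("impute", len(cohort), len(datasets[0]))

    # temperature spline knots located once, on observed values
    knots = {"temp_axillary": list(knot_locations(cohort["temp_axillary"].dropna()))}

    # -- score-component models (MICE-imputed, pooled) -------------------
    report["models"] = {}
    for s in config.scores:
        spec = ModelSpec.for_score(s)
        aucs, vars_ = [], []
        for d in datasets:
            m = fit_logistic(d, spec, knots=knots)
            a, _, v = auc_ci(m.predict_risk(d), d["oxygen_outcome"])
            aucs.append(a)
            vars_.append(v)
        pooled = pool_auc(aucs, vars_)
        opt = bootstrap_optimism(
            datasets[0], spec, B=config.n_bootstrap, seed=config.seed + 23, knots=knots
        )
        report["models"][s] = {
            "pooled_auc": pooled.estimate,
            "pooled_auc_ci": [pooled.ci_lower, pooled.ci_upper],
            "apparent_auc": opt.apparent_auc,
            "optimism": opt.optimism_auc,
            "adjusted_auc": opt.adjusted_auc,
            "adjusted_calibration_slope": opt.adjusted_slope,
            "n_parameters": spec.n_parameters,
        }
    _stage("fit", len(datasets[0]), len(datasets[0]))

    # -- updated models (median-by-outcome completed, lasso) -------------
    completed = median_impute_by_outcome(cohort, impute_vars or list(CANDIDATE_PREDICTORS))
    y_c = completed["oxygen_outcome"].to_numpy(dtype=float)
    grid = default_threshold_grid(*config.dca_grid)
    report["updated_models"] = {}
    report["decision_curves"] = {}
    fitted_models = {}
    for s in config.scores:
        spec_u = ModelSpec.for_score(s, updated=True)
        mu = lasso_update(completed, spec_u, seed=config.seed + 31, knots=knots)
        fitted_models[s] = mu
        risk = mu.predict_risk(completed)
        a, ci, _ = auc_ci(risk, y_c)
        try:
            cal = calibration(risk, y_c)
            cal_out = {"slope": cal.slope, "intercept": cal.intercept}
        except ValueError:
            cal_out = {"slope": None, "intercept": None}
        table4 = classify_at_cutoffs(risk, y_c, config.prob_thresholds)
        dc = decision_curve(risk, y_c, grid)
        report["updated_models"][s] = {
            "auc": a,
            "auc_ci": list(ci),
            "calibration": cal_out,
            "penalty_lambda": mu.penalty,
            "selected_terms": mu.selected_terms,
            "classification": table4.to_dict(orient="records"),
        }
        report["decision_curves"][s] = {
            "threshold": [float(t) for t in dc.thresholds],
            "nb_model": [float(v) for v in dc.nb_model],
            "nb_all": [float(v) for v in dc.nb_all],
        }
    # comparator: best points-based score as a rescaled risk (its own model)
    base_spec = ModelSpec.for_score("lqsofa")
    base = fit_logistic(completed, base_spec, knots=knots)
    dc_base = decision_curve(base.predict_risk(completed), y_c, grid)
    report["decision_curves"]["lqsofa_score_model"] = {
        "threshold": [float(t) for t in dc_base.thresholds],
        "nb_model": [float(v) for v in dc_base.nb_model],
        "nb_all": [float(v) for v in dc_base.nb_all],
    }
    _stage("update+dca", len(completed), len(completed))

    if config.out_dir:
        _write_bundle(Path(config.out_dir), config, report, summary, fitted_models)
    return report


def _write_bundle(out, config, report, summary, fitted_models) -> None:
    out.mkdir(parents=True, exist_ok=True)
    summary.to_csv(out / "cohort_summary.csv", index=False)
    for s, payload in report["scores"].items():
        pd.DataFrame(payload["classification"]).to_csv(
            out / f"table3_{s}.csv", index=False
        )
    for s, payload in report["updated_models"].items():
        pd.DataFrame(payload["classification"]).to_csv(
            out / f"table4_{s}.csv", index=False
        )
    for s, model in fitted_models.items():
        model.to_json(out / f"model_{s}_updated.json")
    dca = []
    for name, curve in report["decision_curves"].items():
        for t, nb, nba in zip(curve["threshold"], curve["nb_model"], curve["nb_all"]):
            dca.append({"model": name, "threshold": t, "nb_model": nb, "nb_all": nba})
    pd.DataFrame(dca).to_csv(out / "decision_curves.csv", index=False)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    log.info("report bundle written to %s", out)
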