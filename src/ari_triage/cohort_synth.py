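"""Seeded synthetic ARI cohort generator.

Real presentation-level data from the source cohort are available only on
request, so every downstream stage of the pipeline is exercised on synthetic
cohorts that reproduce the *statistical structure* the analysis assumes:

* ~756 children aged 0-24 months with repeat clinic visits (22% of children
  present once; visit counts follow a zero-truncated negative binomial
  calibrated to that fraction and the target mean);
* ~3.5% of presentations receive supplemental oxygen (the outcome);
* outcome-conditional vital-sign shifts (tachycardia, tachypnoea, lower
  SpO2, prolonged capillary refill, depressed consciousness, lower
  weight-for-age) matching the published medians and IQRs by moment
  matching;
* child-level random effects so repeat visits are correlated;
* realistic per-field missingness (capillary refill worst at 14.7%),
  applied after outcome assignment so outcomes are always observed.

Two generative modes are supported.  ``table_matched`` (default) draws the
outcome first and vitals from outcome-conditional distributions — good for
realistic demonstrations.  ``score_linked`` draws covariates from the
outcome-negative distributions and generates the outcome from a stated
logistic model whose intercept is calibrated by bisection to hit the target
prevalence — good for parameter-recovery experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from functools import lru_cache
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, special, stats

from .preprocessing import assign_age_band

__all__ = [
    "CohortSpec",
    "generate_cohort",
    "inject_missingness",
    "missingness_summary",
    "write_cohort",
    "read_cohort",
    "DEFAULT_VITAL_PARAMS",
    "DEFAULT_SIGN_PROBS",
    "DEFAULT_MISSINGNESS",
]

_Z75 = stats.norm.ppf(0.75)  # 0.6745; converts an IQR to a normal SD

# (median, q1, q3) by age band and outcome status, from the published
# outcome-stratified cohort characteristics.  HR/RR are modelled log-normal
# (positive, right-skewed), temperature and WAZ normal, SpO2 scaled-beta.
DEFAULT_VITAL_PARAMS: dict = {
    "heart_rate": {
        "dist": "lognormal",
        "by_band": True,
        "neonate": {0: (140.0, 132.0, 148.0), 1: (150.0, 140.0, 165.0)},
        "infant": {0: (136.0, 128.0, 144.0), 1: (147.0, 136.5, 154.0)},
        "child": {0: (128.0, 120.0, 140.0), 1: (140.0, 127.5, 149.0)},
    },
    "resp_rate": {
        "dist": "lognormal",
        "by_band": True,
        "neonate": {0: (48.0, 44.2, 54.0), 1: (64.5, 54.0, 77.0)},
        "infant": {0: (48.0, 42.0, 56.0), 1: (58.0, 54.0, 66.0)},
        "child": {0: (44.0, 38.0, 52.0), 1: (57.0, 46.5, 62.0)},
    },
    "temp_axillary": {
        "dist": "normal",
        "by_band": False,
        "all": {0: (36.6, 36.0, 37.4), 1: (36.8, 36.2, 37.8)},
    },
    "spo2": {
        "dist": "beta100",
        "by_band": False,
        "all": {0: (95.0, 93.0, 96.0), 1: (88.0, 85.0, 93.0)},
    },
    "waz": {
        "dist": "normal",
        "by_band": False,
        "all": {0: (-0.9, -1.6, -0.2), 1: (-1.9, -3.4, -0.8)},
    },
}

# P(sign | outcome status), from the same stratified table.
DEFAULT_SIGN_PROBS: dict = {
    "crt_prolonged": {0: 27 / 2476, 1: 9 / 92},
    "avpu_not_alert": {0: 306 / 2875, 1: 66 / 98},
    "resp_distress": {0: 416 / 2905, 1: 92 / 104},
}

# Per-field missing fractions among the 3010 analysed presentations.
DEFAULT_MISSINGNESS: dict = {
    "heart_rate": 9 / 3010,
    "resp_rate": 8 / 3010,
    "temp_axillary": 3 / 3010,
    "spo2": 1645 / 3010,
    "crt_prolonged": 442 / 3010,
    "avpu_not_alert": 37 / 3010,
    "resp_distress": 1 / 3010,
    "waz": 147 / 3010,
}

#: Admission probability among outcome-negative presentations
#: ((835 admissions - 104 outcome-positive) / 2906).
_P_ADMIT_GIVEN_NO_OXYGEN = (835 - 104) / 2906

_MAR_ALLOWED_FIELDS = ("age_months", "admitted")

VITAL_FIELDS = ("heart_rate", "resp_rate", "temp_axillary", "spo2", "waz")
SIGN_FIELDS = ("crt_prolonged", "avpu_not_alert", "resp_distress")
PREDICTOR_FIELDS = VITAL_FIELDS + SIGN_FIELDS
#: Candidate predictors of the risk models.  SpO2 is excluded: it defines
#: the outcome (oxygen given only when SpO2 < 90%) and is not a predictor.
CANDIDATE_PREDICTORS = tuple(f for f in PREDICTOR_FIELDS if f != "spo2")


@dataclass
class CohortSpec:
    """Full parameterisation of a synthetic cohort.

    Defaults reproduce the study conditions: 756 children, ~3010
    presentations, 3.5% outcome prevalence, 22% of children presenting
    exactly once, published vital-sign shifts and missingness pattern.
    """

    n_children: int = 756
    mean_visits_per_child: float = 3010 / 756
    frac_single_visit: float = 0.22
    outcome_prevalence: float = 104 / 3010
    vital_params: Mapping = field(default_factory=lambda: DEFAULT_VITAL_PARAMS)
    sign_probs: Mapping = field(default_factory=lambda: DEFAULT_SIGN_PROBS)
    missingness: Mapping = field(default_factory=lambda: DEFAULT_MISSINGNESS)
    true_model: Mapping[str, float] | None = None
    mode: str = "table_matched"
    child_effect_icc: float = 0.3
    drop_unknown_outcome_frac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_children <= 0:
            raise ValueError("n_children must be positive")
        if self.mean_visits_per_child < 1:
            raise ValueError("mean_visits_per_child must be >= 1")
        if not 0 <= self.frac_single_visit <= 1:
            raise ValueError("frac_single_visit must be in [0, 1]")
        if not 0 < self.outcome_prevalence < 1:
            raise ValueError("outcome_prevalence must lie strictly in (0, 1)")
        if self.mode not in ("table_matched", "score_linked"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0 <= self.child_effect_icc < 1:
            raise ValueError("child_effect_icc must be in [0, 1)")
        for f, spec in self.missingness.items():
            p = spec["prob"] if isinstance(spec, Mapping) else spec
            if not 0 <= p < 1:
                raise ValueError(f"missingness for {f!r} must be in [0, 1)")
        for sign, probs in self.sign_probs.items():
            for status, p in probs.items():
                if not 0 <= p <= 1:
                    raise ValueError(f"sign_probs[{sign!r}][{status}] outside [0, 1]")
        if self.mode == "score_linked" and not self.true_model:
            raise ValueError("score_linked mode requires a true_model")

    def to_dict(self) -> dict:
        d = {
            "n_children": self.n_children,
            "mean_visits_per_child": self.mean_visits_per_child,
            "frac_single_visit": self.frac_single_visit,
            "outcome_prevalence": self.outcome_prevalence,
            "mode": self.mode,
            "child_effect_icc": self.child_effect_icc,
            "drop_unknown_outcome_frac": self.drop_unknown_outcome_frac,
            "seed": self.seed,
            "true_model": dict(self.true_model) if self.true_model else None,
            "missingness": {
                k: (dict(v) if isinstance(v, Mapping) else float(v))
                for k, v in self.missingness.items()
            },
        }
        return d


# ---------------------------------------------------------------------------
# distribution moment matching


def _lognormal_params(median: float, q1: float, q3: float) -> tuple[float, float]:
    mu = np.log(median)
    sigma = np.log(q3 / q1) / (2 * _Z75)
    return mu, sigma


def _normal_params(median: float, q1: float, q3: float) -> tuple[float, float]:
    return median, (q3 - q1) / (2 * _Z75)


@lru_cache(maxsize=64)
def _beta100_params(median: float, q1: float, q3: float) -> tuple[float, float]:
    """Beta(a, b) scaled to (0, 100]: mean matched to the median, total
    concentration solved so the IQR matches."""
    m = median / 100.0
    target_iqr = (q3 - q1) / 100.0

    def iqr_gap(log_s: float) -> float:
        s = np.exp(log_s)
        a, b = m * s, (1 - m) * s
        return (stats.beta.ppf(0.75, a, b) - stats.beta.ppf(0.25, a, b)) - target_iqr

    # the IQR is not monotone in concentration for very skewed betas, so
    # bracket a sign change on a log grid before root finding
    grid = np.linspace(np.log(0.05), np.log(1e7), 200)
    vals = np.array([iqr_gap(g) for g in grid])
    sign_change = np.flatnonzero(np.diff(np.sign(vals)) != 0)
    if len(sign_change):
        i = sign_change[-1]  # prefer the high-concentration (unimodal) root
        log_s = optimize.brentq(iqr_gap, grid[i], grid[i + 1])
    else:
        log_s = float(grid[np.argmin(np.abs(vals))])
    s = float(np.exp(log_s))
    return m * s, (1 - m) * s


# ---------------------------------------------------------------------------
# visit-count distribution


@lru_cache(maxsize=16)
def _ztnb_pmf(mean_visits: float, frac_single: float, kmax: int = 100) -> tuple:
    """Zero-truncated negative binomial pmf over 1..kmax with P(1) and the
    mean matched to the targets (solved numerically)."""

    def moments(params):
        log_r, logit_p = params
        r, p = np.exp(log_r), special.expit(logit_p)
        p0 = p**r
        mean_t = r * (1 - p) / p / (1 - p0)
        p1 = r * p**r * (1 - p) / (1 - p0)
        return mean_t, p1

    def residuals(params):
        mean_t, p1 = moments(params)
        return [mean_t - mean_visits, p1 - frac_single]

    sol = optimize.fsolve(residuals, x0=[0.0, -1.0], full_output=True)
    x, _, ier, _ = sol
    if ier != 1 or max(abs(np.array(residuals(x)))) > 1e-6:
        raise RuntimeError(
            "could not calibrate visit-count distribution to "
            f"mean={mean_visits}, P(single)={frac_single}"
        )
    r, p = np.exp(x[0]), special.expit(x[1])
    k = np.arange(1, kmax + 1)
    pmf = stats.nbinom.pmf(k, r, p)
    pmf = pmf / pmf.sum()
    return tuple(pmf)


def _draw_visit_counts(rng: np.random.Generator, spec: CohortSpec) -> np.ndarray:
    if spec.mean_visits_per_child == 1.0:
        return np.ones(spec.n_children, dtype=int)
    pmf = np.array(_ztnb_pmf(spec.mean_visits_per_child, spec.frac_single_visit))
    return rng.choice(np.arange(1, len(pmf) + 1), size=spec.n_children, p=pmf)


# ---------------------------------------------------------------------------
# vital-sign sampling


def _vital_triple(vspec: Mapping, band: str, status: int) -> tuple[float, float, float]:
    return vspec[band][status] if vspec["by_band"] else vspec["all"][status]


def _sample_vital(
    rng: np.random.Generator,
    vspec: Mapping,
    bands: np.ndarray,
    status: np.ndarray,
    child_effect: np.ndarray,
    icc: float,
) -> np.ndarray:
    """Draw one vital for all presentations.

    ``child_effect`` is a per-presentation standard-normal value shared by
    all visits of a child; it contributes a fraction ``icc`` of the latent
    variance so repeat visits are correlated.
    """
    n = len(bands)
    resid = rng.standard_normal(n)
    z = np.sqrt(icc) * child_effect + np.sqrt(1 - icc) * resid
    out = np.empty(n)
    dist = vspec["dist"]
    band_keys = ("neonate", "infant", "child") if vspec["by_band"] else ("all",)
    for band in band_keys:
        for st in (0, 1):
            mask = (status == st) if band == "all" else (bands == band) & (status == st)
            if not mask.any():
                continue
            med, q1, q3 = _vital_triple(vspec, band, st)
            if dist == "lognormal":
                mu, sigma = _lognormal_params(med, q1, q3)
                out[mask] = np.exp(mu + sigma * z[mask])
            elif dist == "normal":
                mu, sigma = _normal_params(med, q1, q3)
                out[mask] = mu + sigma * z[mask]
            elif dist == "beta100":
                a, b = _beta100_params(med, q1, q3)
                u = stats.norm.cdf(z[mask])
                out[mask] = 100.0 * stats.beta.ppf(u, a, b)
            else:
                raise ValueError(f"unknown distribution {dist!r}")
    return out


def _calibrate_intercept(lp_no_intercept: np.ndarray, prevalence: float) -> float:
    """Bisection on the logistic intercept so the mean event probability
    equals the target prevalence."""

    def gap(c: float) -> float:
        return float(special.expit(lp_no_intercept + c).mean() - prevalence)

    return optimize.brentq(gap, -40.0, 40.0)


# ---------------------------------------------------------------------------
# public API


def generate_cohort(spec: CohortSpec, seed: int | None = None) -> pd.DataFrame:
    """Generate a presentation-level cohort table.

    One row per clinic visit, columns: ``child_id``, ``visit_id``,
    ``visit_date``, ``sex``, ``age_months``, ``age_band``, vital signs,
    clinical signs, ``waz``, ``admitted``, ``oxygen_outcome``.  Reproducible
    for a fixed spec and seed (``seed`` overrides ``spec.seed`` if given).
    Missingness is applied to predictors only, after outcome assignment.
    """
    if seed is not None:
        spec = replace(spec, seed=seed)
    rng = np.random.default_rng(spec.seed)

    counts = _draw_visit_counts(rng, spec)
    n = int(counts.sum())
    child_idx = np.repeat(np.arange(spec.n_children), counts)
    child_ids = np.array([f"C{i + 1:04d}" for i in range(spec.n_children)])

    # ages: sorted uniform over 0-24 months within each child
    ages = rng.uniform(0.0, 24.0, size=n)
    order = np.lexsort((ages, child_idx))
    ages = ages[order]
    bands = assign_age_band(ages)

    visit_no = np.concatenate([np.arange(1, c + 1) for c in counts])
    sex = np.where(rng.random(spec.n_children) < 0.53, "M", "F")[child_idx]

    # per-child latent effects, one per vital (shared across that child's visits)
    child_fx = {v: rng.standard_normal(spec.n_children)[child_idx] for v in VITAL_FIELDS}

    if spec.mode == "table_matched":
        outcome = (rng.random(n) < spec.outcome_prevalence).astype(int)
        vitals = {
            v: _sample_vital(rng, spec.vital_params[v], bands, outcome,
                             child_fx[v], spec.child_effect_icc)
            for v in VITAL_FIELDS
        }
        signs = {
            s: (rng.random(n) < np.where(outcome == 1, spec.sign_probs[s][1],
                                         spec.sign_probs[s][0])).astype(float)
            for s in SIGN_FIELDS
        }
    else:  # score_linked
        neutral = np.zeros(n, dtype=int)  # covariates from outcome-negative laws
        vitals = {
            v: _sample_vital(rng, spec.vital_params[v], bands, neutral,
                             child_fx[v], spec.child_effect_icc)
            for v in VITAL_FIELDS
        }
        signs = {
            s: (rng.random(n) < spec.sign_probs[s][0]).astype(float)
            for s in SIGN_FIELDS
        }
        columns = {**vitals, **signs, "age_months": ages}
        lp = np.zeros(n)
        for name, coef in spec.true_model.items():
            if name == "intercept":
                continue
            if name not in columns:
                raise KeyError(f"true_model refers to unknown covariate {name!r}")
            lp += coef * columns[name]
        intercept = _calibrate_intercept(lp, spec.outcome_prevalence)
        outcome = (rng.random(n) < special.expit(lp + intercept)).astype(int)

    admitted = np.where(
        outcome == 1, 1, (rng.random(n) < _P_ADMIT_GIVEN_NO_OXYGEN).astype(int)
    )

    start = date(2007, 9, 1)
    birth_offset = rng.integers(0, 365, size=spec.n_children)[child_idx]
    visit_dates = [
        (start + timedelta(days=int(b) + int(round(a * 30.44)))).isoformat()
        for b, a in zip(birth_offset, ages)
    ]

    df = pd.DataFrame(
        {
            "child_id": child_ids[child_idx],
            "visit_id": [f"{c}-V{v:02d}" for c, v in zip(child_ids[child_idx], visit_no)],
            "visit_date": visit_dates,
            "sex": sex,
            "age_months": ages,
            "age_band": bands,
            "heart_rate": vitals["heart_rate"],
            "resp_rate": vitals["resp_rate"],
            "temp_axillary": vitals["temp_axillary"],
            "spo2": vitals["spo2"],
            "crt_prolonged": signs["crt_prolonged"],
            "avpu_not_alert": signs["avpu_not_alert"],
            "resp_distress": signs["resp_distress"],
            "waz": vitals["waz"],
            "admitted": admitted,
            "oxygen_outcome": outcome,
        }
    )

    if spec.drop_unknown_outcome_frac > 0:
        keep = rng.random(n) >= spec.drop_unknown_outcome_frac
        df = df.loc[keep].reset_index(drop=True)

    df = inject_missingness(df, spec.missingness, rng=rng)
    df.attrs["spec"] = spec.to_dict()
    return df


def inject_missingness(
    records: pd.DataFrame,
    missingness_spec: Mapping,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Blank predictor cells at the specified rates (MCAR or MAR).

    ``missingness_spec`` maps field name to either a plain probability
    (MCAR) or a mapping ``{"prob": p, "mar": {"on": field, "lt"/"ge": x,
    "multiplier": m}}`` where the per-row probability becomes ``p*m`` when
    the condition holds.  MAR dependence is only allowed on always-observed
    fields (``age_months``, ``admitted``); dependence on the outcome or on
    any field that can itself be missing is rejected.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    out = records.copy()
    for fld, fspec in missingness_spec.items():
        if fld not in out.columns:
            raise KeyError(f"missingness spec names unknown field {fld!r}")
        if isinstance(fspec, Mapping):
            p = float(fspec["prob"])
            mar = fspec.get("mar")
        else:
            p, mar = float(fspec), None
        if not 0 <= p < 1:
            raise ValueError(f"missingness probability for {fld!r} must be in [0, 1)")
        prob = np.full(len(out), p)
        if mar is not None:
            on = mar["on"]
            if on not in _MAR_ALLOWED_FIELDS:
                raise ValueError(
                    f"MAR dependence on {on!r} not allowed; must be one of "
                    f"{_MAR_ALLOWED_FIELDS} (always observed, not the outcome)"
                )
            cond = np.ones(len(out), dtype=bool)
            if "lt" in mar:
                cond &= out[on].to_numpy() < mar["lt"]
            if "ge" in mar:
                cond &= out[on].to_numpy() >= mar["ge"]
            prob = np.where(cond, p * float(mar.get("multiplier", 1.0)), prob)
            if (prob >= 1).any():
                raise ValueError(f"MAR-adjusted missingness for {fld!r} reaches 1")
        if p == 0 and mar is None:
            continue
        mask = rng.random(len(out)) < prob
        if mask.any():
            col = out[fld].astype(float) if out[fld].dtype != float else out[fld].copy()
            col[mask] = np.nan
            out[fld] = col
    return out


def missingness_summary(
    records: pd.DataFrame, predictors: tuple[str, ...] = CANDIDATE_PREDICTORS
) -> pd.Series:
    """Per-predictor missing fraction plus the fraction of presentations
    with at least one missing candidate predictor (key ``any_predictor``).

    The default predictor set excludes SpO2, which qualifies the outcome
    rather than predicting it.
    """
    present = [p for p in predictors if p in records.columns]
    fracs = records[present].isna().mean()
    fracs["any_predictor"] = records[present].isna().any(axis=1).mean()
    return fracs


def write_cohort(df: pd.DataFrame, spec: CohortSpec, csv_path, sidecar_path=None) -> None:
    """Write a cohort as CSV (RFC 4180, UTF-8, ISO-8601 dates) with a YAML
    sidecar holding the full generating spec and seed."""
    df.to_csv(csv_path, index=False)
    sidecar = sidecar_path or str(csv_path) + ".yaml"
    with open(sidecar, "w") as fh:
        yaml.safe_dump(spec.to_dict(), fh, sort_keys=False)


def read_cohort(csv_path) -> pd.DataFrame:
    df = pd.read_csv(csv_path)
    if "age_band" not in df.columns and "age_months" in df.columns:
        df["age_band"] = assign_age_band(df["age_months"].to_numpy())
    return df
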