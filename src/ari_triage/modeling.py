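"""Risk-model derivation and internal validation.

Each points-based severity score is converted into a logistic clinical
prediction model on its own component variables: binary signs enter as
indicators, heart and respiratory rate as continuous terms (per 10
beats/breaths per minute), temperature as a restricted cubic spline with
three knots (5th percentile, 36 degrees C, 95th percentile), and age in
months as a main effect.  Updated models additionally offer weight-for-age
z-score and respiratory distress as candidate predictors, fitted by lasso
(L1-penalised) logistic regression with the penalty chosen by 10-fold
cross-validated deviance.

Internal validation follows Harrell's bootstrap optimism procedure: refit
on each resample, score the resample-fit on both the resample and the
original data, average the difference, and subtract it from the apparent
performance (AUC and calibration slope).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import special, stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .evaluation import calibration_slope, roc_auc

__all__ = [
    "ModelSpec",
    "FittedRiskModel",
    "rcs_basis",
    "knot_locations",
    "build_design",
    "fit_logistic",
    "lrt_interaction",
    "bootstrap_optimism",
    "OptimismResult",
    "lasso_update",
    "epp",
    "lowess_explore",
]

MAX_PARAMETERS = 13  # overfitting guard: events-per-parameter budget

# component variables of each score that enter its prediction model
_SCORE_BINARY = {
    "lqsofa": ["crt_prolonged", "avpu_not_alert"],
    "qpelod2": ["avpu_not_alert", "crt_prolonged"],
    "msirs": [],
}
_SCORE_CONTINUOUS = {
    "lqsofa": ["heart_rate", "resp_rate"],
    "qpelod2": ["heart_rate"],
    "msirs": ["heart_rate", "resp_rate"],
}
_SCORE_SPLINE = {
    "lqsofa": [],
    "qpelod2": [],
    "msirs": ["temp_axillary"],
}

_RATE_SCALE = 10.0  # HR/RR coefficients are per 10 beats/breaths per minute


@dataclass
class ModelSpec:
    """Terms of one risk model.

    ``continuous`` variables named ``heart_rate``/``resp_rate`` are scaled
    per 10 units; ``spline`` variables get a 3-knot restricted cubic
    basis (2 columns).  ``extra_terms`` holds the updating candidates
    (``waz``, ``resp_distress``).
    """

    name: str
    binary: list[str] = field(default_factory=list)
    continuous: list[str] = field(default_factory=list)
    spline: list[str] = field(default_factory=list)
    extra_terms: list[str] = field(default_factory=list)
    include_age_main_effect: bool = True
    outcome: str = "oxygen_outcome"

    @classmethod
    def for_score(cls, score: str, updated: bool = False, **kwargs) -> "ModelSpec":
        if score not in _SCORE_BINARY:
            raise ValueError(f"unknown score {score!r}")
        return cls(
            name=f"{score}_updated" if updated else score,
            binary=list(_SCORE_BINARY[score]),
            continuous=list(_SCORE_CONTINUOUS[score]),
            spline=list(_SCORE_SPLINE[score]),
            extra_terms=["waz", "resp_distress"] if updated else [],
            **kwargs,
        )

    @property
    def n_parameters(self) -> int:
        """Number of non-intercept parameters."""
        return (
            len(self.binary)
            + len(self.continuous)
            + 2 * len(self.spline)
            + len(self.extra_terms)
            + int(self.include_age_main_effect)
        )

    def __post_init__(self) -> None:
        if self.n_parameters > MAX_PARAMETERS:
            raise ValueError(
                f"{self.n_parameters} parameters exceeds the "
                f"{MAX_PARAMETERS}-parameter overfitting guard"
            )

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "binary": list(self.binary),
            "continuous": list(self.continuous),
            "spline": list(self.spline),
            "extra_terms": list(self.extra_terms),
            "include_age_main_effect": self.include_age_main_effect,
            "outcome": self.outcome,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelSpec":
        return cls(**dict(d))


# ---------------------------------------------------------------------------
# restricted cubic splines


def rcs_basis(x, knots: Sequence[float]) -> np.ndarray:
    """Harrell-form restricted cubic spline basis for 3 knots.

    Returns two columns: the identity term and a truncated-cubic
    combination that is zero below the first knot, cubic between the
    boundary knots, and exactly linear beyond the last knot; normalised by
    ``(k3 - k1)**2`` so the coefficient scale matches the linear term.
    """
    k1, k2, k3 = (float(k) for k in knots)
    if not k1 < k2 < k3:
        raise ValueError("knots must be strictly ascending and distinct")
    x = np.asarray(x, dtype=float)

    def tp3(k: float) -> np.ndarray:
        return np.clip(x - k, 0.0, None) ** 3

    c2 = (
        tp3(k1)
        - tp3(k2) * (k3 - k1) / (k3 - k2)
        + tp3(k3) * (k2 - k1) / (k3 - k2)
    ) / (k3 - k1) ** 2
    return np.column_stack([x, c2])


def knot_locations(temps, physiological: float = 36.0) -> np.ndarray:
    """Knots for the temperature spline: 5th percentile, 36 degrees C,
    95th percentile.

    Falls back to {p5, median, p95} (with a warning) when 36 lies outside
    (p5, p95) or within 0.1 of either boundary knot.  Requires at least 20
    observed values; degenerate (near-constant) temperatures raise.
    """
    t = np.asarray(temps, dtype=float)
    t = t[~np.isnan(t)]
    if t.size < 20:
        raise ValueError(f"need >= 20 observed temperatures, got {t.size}")
    p5, p50, p95 = np.percentile(t, [5, 50, 95])
    if p95 - p5 < 1e-9:
        raise ValueError("degenerate temperature distribution: percentiles coincide")
    if p5 + 0.1 < physiological < p95 - 0.1:
        return np.array(sorted([p5, physiological, p95]))
    warnings.warn(
        f"physiological knot {physiological} too close to boundary percentiles "
        f"({p5:.2f}, {p95:.2f}); falling back to percentile knots",
        stacklevel=2,
    )
    if not p5 < p50 < p95:
        raise ValueError("degenerate temperature distribution: median at a boundary")
    return np.array([p5, p50, p95])


# ---------------------------------------------------------------------------
# design matrix


def build_design(
    data: pd.DataFrame,
    spec: ModelSpec,
    knots: Mapping[str, Sequence[float]] | None = None,
) -> tuple[pd.DataFrame, dict[str, list[float]]]:
    """Design matrix (without intercept) for ``spec``.

    ``knots`` maps spline variable -> 3 knots; missing entries are located
    from the data.  Returns ``(X, knots_used)``.
    """
    cols: dict[str, np.ndarray] = {}
    knots = dict(knots or {})
    for v in spec.continuous:
        scale = _RATE_SCALE if v in ("heart_rate", "resp_rate") else 1.0
        cols[f"{v}_per10" if scale == 10.0 else v] = data[v].to_numpy(dtype=float) / scale
    for v in spec.spline:
        if v not in knots:
            knots[v] = list(knot_locations(data[v].to_numpy(dtype=float)))
        basis = rcs_basis(data[v].to_numpy(dtype=float), knots[v])
        cols[f"{v}_rcs1"] = basis[:, 0]
        cols[f"{v}_rcs2"] = basis[:, 1]
    for v in spec.binary + spec.extra_terms:
        cols[v] = data[v].to_numpy(dtype=float)
    if spec.include_age_main_effect:
        cols["age_months"] = data["age_months"].to_numpy(dtype=float)
    X = pd.DataFrame(cols, index=data.index)
    return X, {k: [float(x) for x in v] for k, v in knots.items()}


# ---------------------------------------------------------------------------
# fitted model container


@dataclass
class FittedRiskModel:
    """A fitted logistic risk model: coefficients, spline knots, penalty
    and training metadata.  ``penalty`` is the lasso lambda (0 = maximum
    likelihood)."""

    spec: ModelSpec
    coefficients: dict[str, float]  # includes "const"
    knots: dict[str, list[float]]
    penalty: float = 0.0
    training_n: int = 0
    training_events: int = 0
    apparent_auc: float | None = None
    optimism: float | None = None
    adjusted_auc: float | None = None
    calibration_slope: float | None = None
    extra: dict = field(default_factory=dict)

    def linear_predictor(self, data: pd.DataFrame) -> np.ndarray:
        X, _ = build_design(data, self.spec, knots=self.knots)
        lp = np.full(len(X), self.coefficients["const"])
        for name, beta in self.coefficients.items():
            if name != "const":
                lp += beta * X[name].to_numpy()
        return lp

    def predict_risk(self, data: pd.DataFrame) -> np.ndarray:
        return special.expit(self.linear_predictor(data))

    @property
    def selected_terms(self) -> list[str]:
        """Non-intercept terms with non-zero coefficients (lasso models
        report dropped terms as not selected)."""
        return [k for k, v in self.coefficients.items() if k != "const" and v != 0.0]

    def to_json(self, path=None) -> str:
        payload = {
            "spec": self.spec.to_dict(),
            "coefficients": self.coefficients,
            "knots": self.knots,
            "penalty": self.penalty,
            "training_n": self.training_n,
            "training_events": self.training_events,
            "apparent_auc": self.apparent_auc,
            "optimism": self.optimism,
            "adjusted_auc": self.adjusted_auc,
            "calibration_slope": self.calibration_slope,
            "extra": {k: v for k, v in self.extra.items() if _json_safe(v)},
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "FittedRiskModel":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        payload["spec"] = ModelSpec.from_dict(payload["spec"])
        return cls(**payload)


def _json_safe(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


# ---------------------------------------------------------------------------
# maximum-likelihood fitting


def _check_outcome(y: np.ndarray) -> None:
    classes = set(np.unique(y))
    if not classes.issubset({0.0, 1.0}):
        raise ValueError("outcome must be binary 0/1")
    if len(classes) < 2:
        raise ValueError("outcome has a single class; cannot fit")


def fit_logistic(
    dataset: pd.DataFrame,
    spec: ModelSpec,
    knots: Mapping[str, Sequence[float]] | None = None,
    ridge: float = 0.0,
) -> FittedRiskModel:
    """Maximum-likelihood logistic fit of ``spec`` on ``dataset``.

    Requires a complete dataset (impute upstream) with both outcome
    classes.  Raises on rank deficiency and on detected separation
    (diverging coefficients), advising penalisation; ``ridge > 0`` applies
    an L2 penalty of that strength instead of plain MLE (used for
    degenerate resamples during bootstrapping).
    """
    y = dataset[spec.outcome].to_numpy(dtype=float)
    _check_outcome(y)
    X, knots_used = build_design(dataset, spec, knots=knots)
    if X.isna().any().any():
        raise ValueError("design matrix contains missing values; impute first")
    if X.shape[1] > 0:
        rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X.to_numpy()]))
        if rank < X.shape[1] + 1:
            raise ValueError("design matrix is rank deficient")

    if ridge > 0:
        clf = LogisticRegression(C=1.0 / (ridge * len(y)), max_iter=2000)
        clf.fit(X.to_numpy(), y)
        params = np.concatenate([clf.intercept_, clf.coef_.ravel()])
    else:
        Xd = sm.add_constant(X.to_numpy()) if X.shape[1] else np.ones((len(y), 1))
        model = sm.Logit(y, Xd)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = model.fit(disp=0, method="newton", maxiter=200, tol=1e-10)
            except Exception as exc:  # PerfectSeparationError and friends
                raise ValueError(
                    "logistic fit failed (possible separation); consider a "
                    "penalised fit (ridge > 0)"
                ) from exc
        params = np.asarray(res.params)
        if not res.mle_retvals.get("converged", True) or np.abs(params).max() > 50:
            raise ValueError(
                "separation detected (diverging coefficients); consider a "
                "penalised fit (ridge > 0)"
            )

    coefs = {"const": float(params[0])}
    coefs.update({c: float(b) for c, b in zip(X.columns, params[1:])})
    fitted = FittedRiskModel(
        spec=spec,
        coefficients=coefs,
        knots=knots_used,
        penalty=0.0,
        training_n=int(len(y)),
        training_events=int(y.sum()),
    )
    risk = fitted.predict_risk(dataset)
    fitted.apparent_auc = roc_auc(risk, y) if X.shape[1] else None
    fitted.extra["loglik"] = float(_bernoulli_loglik(y, risk))
    fitted.extra["ridge"] = ridge
    return fitted


def _bernoulli_loglik(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def lrt_interaction(
    dataset: pd.DataFrame,
    base_spec: ModelSpec,
    term_a: str,
    term_b: str,
    knots: Mapping[str, Sequence[float]] | None = None,
) -> tuple[float, int, float]:
    """Likelihood-ratio test for adding the ``term_a`` x ``term_b``
    interaction to ``base_spec``.

    Terms are named as design-matrix columns (e.g. ``heart_rate_per10``,
    ``age_months``).  Returns ``(statistic, df, p)``; if the product column
    adds no rank (e.g. it duplicates an existing column) the models are
    identical and the test is (0, 0, 1).
    """
    y = dataset[base_spec.outcome].to_numpy(dtype=float)
    _check_outcome(y)
    X, knots_used = build_design(dataset, base_spec, knots=knots)

    def col(term: str) -> np.ndarray:
        if term in X.columns:
            return X[term].to_numpy()
        if term in dataset.columns:
            return dataset[term].to_numpy(dtype=float)
        raise KeyError(f"interaction term {term!r} not found in design or data")

    product = col(term_a) * col(term_b)
    Xd = np.column_stack([np.ones(len(X)), X.to_numpy()])
    X_full = np.column_stack([Xd, product])
    if np.linalg.matrix_rank(X_full) <= np.linalg.matrix_rank(Xd):
        return 0.0, 0, 1.0

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ll_reduced = sm.Logit(y, Xd).fit(disp=0, maxiter=200).llf
        ll_full = sm.Logit(y, X_full).fit(disp=0, maxiter=200).llf
    stat = max(0.0, 2.0 * (ll_full - ll_reduced))
    df = 1
    p = float(stats.chi2.sf(stat, df))
    return float(stat), df, p


# ---------------------------------------------------------------------------
# bootstrap optimism correction


@dataclass
class OptimismResult:
    apparent_auc: float
    optimism_auc: float
    adjusted_auc: float
    apparent_slope: float
    optimism_slope: float
    adjusted_slope: float
    B: int
    n_redrawn: int


def bootstrap_optimism(
    dataset: pd.DataFrame,
    spec: ModelSpec,
    B: int = 100,
    seed: int = 0,
    knots: Mapping[str, Sequence[float]] | None = None,
    ridge: float = 0.0,
) -> OptimismResult:
    """Harrell's bootstrap optimism correction of AUC and calibration slope.

    For each of ``B`` resamples with replacement: refit, evaluate the
    resample-fit on the resample (apparent) and on the original data
    (test); optimism is the mean difference and the adjusted value is the
    original apparent performance minus the optimism.  The apparent
    calibration slope of an MLE fit on its own training data is exactly 1.
    Resamples with a single outcome class (or a failed fit) are redrawn,
    at most 10 times each.
    """
    y = dataset[spec.outcome].to_numpy(dtype=float)
    _check_outcome(y)
    if y.sum() < 10:
        raise ValueError("need at least 10 events for bootstrap validation")
    original = fit_logistic(dataset, spec, knots=knots, ridge=ridge)
    knots_used = original.knots
    risk_orig = original.predict_risk(dataset)
    apparent_auc = roc_auc(risk_orig, y)
    apparent_slope = 1.0 if ridge == 0 else calibration_slope(risk_orig, y)

    rng = np.random.default_rng(seed)
    n = len(dataset)
    opt_auc, opt_slope = [], []
    n_redrawn = 0
    for _ in range(B):
        for attempt in range(11):
            idx = rng.integers(0, n, size=n)
            yb = y[idx]
            if len(np.unique(yb)) < 2:
                n_redrawn += 1
                continue
            boot = dataset.iloc[idx].reset_index(drop=True)
            try:
                mb = fit_logistic(boot, spec, knots=knots_used, ridge=ridge)
            except ValueError:
                n_redrawn += 1
                continue
            break
        else:
            raise RuntimeError("bootstrap resample failed more than 10 times in a row")
        risk_bb = mb.predict_risk(boot)
        risk_bo = mb.predict_risk(dataset)
        opt_auc.append(roc_auc(risk_bb, yb) - roc_auc(risk_bo, y))
        slope_bb = 1.0 if ridge == 0 else calibration_slope(risk_bb, yb)
        try:
            slope_bo = calibration_slope(risk_bo, y)
        except ValueError:
            slope_bo = slope_bb
        opt_slope.append(slope_bb - slope_bo)

    o_auc = float(np.mean(opt_auc))
    o_slope = float(np.mean(opt_slope))
    return OptimismResult(
        apparent_auc=float(apparent_auc),
        optimism_auc=o_auc,
        adjusted_auc=float(apparent_auc - o_auc),
        apparent_slope=float(apparent_slope),
        optimism_slope=o_slope,
        adjusted_slope=float(apparent_slope - o_slope),
        B=B,
        n_redrawn=n_redrawn,
    )


# ---------------------------------------------------------------------------
# lasso updating


def _deviance(y: np.ndarray, p: np.ndarray) -> float:
    return -2.0 * _bernoulli_loglik(y, p) / len(y)


def _lasso_fit_std(
    Xs: np.ndarray, y: np.ndarray, lam: float, tight: bool = False
) -> tuple[np.ndarray, float]:
    """L1-penalised logistic fit on standardised columns; the intercept is
    unpenalised.  ``lam`` is on the glmnet scale (per-observation).
    ``tight`` requests a stricter tolerance (final fits); cross-validation
    fits use a looser one for speed."""
    if lam <= 0:
        clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=10000, tol=1e-12)
    else:
        C = 1.0 / (lam * len(y))
        clf = LogisticRegression(
            l1_ratio=1.0,
            C=C,
            solver="saga",
            max_iter=20000 if tight else 3000,
            tol=1e-7 if tight else 1e-5,
            random_state=0,  # saga shuffles; pin for reproducibility
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # saga convergence chatter at small lambda
        clf.fit(Xs, y)
    coef = clf.coef_.ravel()
    icpt = float(clf.intercept_[0])
    if lam > 0:
        # saga leaves the (unpenalised) intercept short of its optimum under
        # heavy penalties; solve its score equation exactly given the slopes
        offset = Xs @ coef
        ybar = y.mean()

        def score(c: float) -> float:
            return float(special.expit(c + offset).mean() - ybar)

        from scipy import optimize

        icpt = float(optimize.brentq(score, icpt - 20.0, icpt + 20.0))
    return coef, icpt


def lasso_update(
    dataset: pd.DataFrame,
    spec: ModelSpec,
    seed: int = 0,
    lam: float | None = None,
    n_folds: int = 10,
    lambda_rule: str = "1se",
    n_lambdas: int = 30,
    knots: Mapping[str, Sequence[float]] | None = None,
) -> FittedRiskModel:
    """Model updating by lasso logistic regression.

    Requires a complete dataset (the pipeline uses outcome-grouped median
    imputation upstream so selection is not fragmented across imputed
    datasets).  Columns are standardised internally; reported coefficients
    are on the original scale and the intercept is unpenalised.  With
    ``lam=None`` the penalty is chosen by ``n_folds``-fold cross-validated
    deviance using the 1-SE rule (``lambda_rule="min"`` for the minimiser);
    both candidate lambdas are recorded in ``extra``.
    """
    y = dataset[spec.outcome].to_numpy(dtype=float)
    _check_outcome(y)
    X, knots_used = build_design(dataset, spec, knots=knots)
    if X.isna().any().any():
        raise ValueError("design matrix contains missing values; impute first")
    Xn = X.to_numpy()
    mean = Xn.mean(axis=0)
    sd = Xn.std(axis=0)
    if (sd == 0).any():
        bad = [c for c, s in zip(X.columns, sd) if s == 0]
        raise ValueError(f"constant design columns: {bad}")
    Xs = (Xn - mean) / sd

    extra: dict = {}
    if lam is None:
        if int(y.sum()) < n_folds:
            raise ValueError(
                f"{int(y.sum())} events is fewer than {n_folds} folds; "
                "reduce n_folds"
            )
        lam_max = float(np.abs(Xs.T @ (y - y.mean())).max() / len(y))
        lambdas = np.geomspace(lam_max, lam_max * 1e-4, n_lambdas)
        folds = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        dev = np.zeros((n_folds, n_lambdas))
        for f, (tr, va) in enumerate(folds.split(Xs, y)):
            for j, l in enumerate(lambdas):
                coef, icpt = _lasso_fit_std(Xs[tr], y[tr], l)
                p = special.expit(Xs[va] @ coef + icpt)
                dev[f, j] = _deviance(y[va], p)
        mean_dev = dev.mean(axis=0)
        se_dev = dev.std(axis=0, ddof=1) / np.sqrt(n_folds)
        j_min = int(np.argmin(mean_dev))
        within = mean_dev <= mean_dev[j_min] + se_dev[j_min]
        j_1se = int(np.flatnonzero(within)[0])  # largest lambda within 1 SE
        extra["lambda_min"] = float(lambdas[j_min])
        extra["lambda_1se"] = float(lambdas[j_1se])
        extra["cv_deviance"] = [float(v) for v in mean_dev]
        extra["cv_lambdas"] = [float(v) for v in lambdas]
        lam = float(lambdas[j_1se] if lambda_rule == "1se" else lambdas[j_min])

    coef_std, icpt_std = _lasso_fit_std(Xs, y, lam, tight=True)
    beta = coef_std / sd
    const = icpt_std - float(mean @ beta)
    coefs = {"const": float(const)}
    coefs.update({c: float(b) for c, b in zip(X.columns, beta)})

    fitted = FittedRiskModel(
        spec=spec,
        coefficients=coefs,
        knots=knots_used,
        penalty=float(lam),
        training_n=int(len(y)),
        training_events=int(y.sum()),
        extra=extra,
    )
    fitted.apparent_auc = (
        roc_auc(fitted.predict_risk(dataset), y) if any(beta != 0) else None
    )
    return fitted


# ---------------------------------------------------------------------------
# small utilities


def epp(events: int, n_parameters: int) -> int:
    """Events per parameter, floored: the overfitting budget check."""
    if n_parameters < 1:
        raise ValueError("n_parameters must be >= 1")
    if events < 0:
        raise ValueError("events must be non-negative")
    return int(events // n_parameters)


def lowess_explore(x, y_binary, bandwidth: float = 2 / 3) -> np.ndarray:
    """LOWESS smoother of outcome fraction over a continuous predictor.

    Used before model building to spot non-linear predictor-outcome
    relationships.  Returns an (n, 2) array of (grid, smoothed fraction)
    pairs sorted by x; a bandwidth of 1.0 approaches a global linear fit.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y_binary, dtype=float)
    if len(x) < 50:
        raise ValueError("need at least 50 points for LOWESS exploration")
    if np.ptp(x) < 1e-12:
        raise ValueError("constant predictor: LOWESS undefined")
    # it=0: robustifying iterations would treat the (rare) events as
    # outliers and bias the smoothed fraction toward zero
    return _sm_lowess(y, x, frac=bandwidth, it=0, return_sorted=True)
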