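# Methods

This note documents the statistical procedures implemented in
`ari_triage`, the generative model behind the synthetic cohorts, the
defaults and where they come from, and the numerical choices a user
should know before interpreting output.

## 1. Problem setting

Young children (≤ 24 months) present to a primary care clinic with acute
respiratory infections. A minority will deteriorate and need supplemental
oxygen; the clinic's protocol ties oxygen to measured SpO₂ < 90%, making
"received oxygen during the illness visit" a reasonably objective binary
outcome with ~3.5% prevalence. The task is to validate three points-based
severity scores (LqSOFA, adapted qPELOD-2, mSIRS) for guiding referral,
then quantify what is gained by (a) refitting each score's components as
a logistic prediction model and (b) updating that model with nutritional
status (weight-for-age z-score, WAZ) and respiratory distress.

## 2. Synthetic cohort generator

Presentation-level cohorts of this kind are access-restricted, so the
package ships a seeded generator whose defaults encode the study
conditions rather than convenient ones.

**Structure.** 756 children; visit counts per child follow a
zero-truncated negative binomial solved numerically so that
P(1 visit) = 0.22 and the mean ≈ 3010/756 ≈ 3.98. Visit ages are uniform
over 0–24 months, sorted within child. Age bands: neonate < 1 month,
infant 1 to < 12 months, child 12–24 months (conventional cuts; the
stratified vital-sign tables in this literature use these bands without
printing them).

**Vitals.** Heart and respiratory rate are log-normal (positive support,
right skew), temperature and WAZ normal, SpO₂ a beta distribution scaled
to (0, 100]. Parameters are moment-matched to published outcome-stratified
medians and IQRs (e.g. infant RR 48 (42–56) outcome-negative vs 58
(54–66) outcome-positive; SpO₂ 95 (93–96) vs 88 (85–93)). A per-child
standard-normal effect contributes 30% of each vital's latent variance
(`child_effect_icc`), so repeat visits are correlated.

**Signs.** Prolonged capillary refill, AVPU below alert and respiratory
distress are Bernoulli draws with outcome-conditional probabilities taken
from the same stratified table (e.g. respiratory distress 14.3% vs
88.5%).

**Outcome.** Two modes:

- `table_matched` (default): the outcome is drawn first at the target
  prevalence and vitals follow their outcome-conditional laws. Good for
  realistic demonstrations; the implied predictor-outcome association is
  whatever the conditional shifts produce.
- `score_linked`: covariates are drawn from the outcome-negative laws and
  the outcome follows a user-stated logistic model; the intercept is
  calibrated by bisection so the mean event probability equals the target
  prevalence. Good for parameter-recovery and selection experiments,
  because the truth is known.

**Missingness** is injected after outcome assignment (outcome, age and
admission status are always observed). Defaults are the published
per-field missing fractions (capillary refill 442/3010 = 14.7%, WAZ 4.9%,
AVPU 1.2%, HR/RR/temperature < 0.5%, SpO₂ 54.6%). MCAR by default; a MAR
mechanism can scale any field's rate conditional on always-observed
fields only (age, admission) — dependence on the outcome or on a missable
field is rejected. SpO₂ is *not* a candidate predictor (it qualifies the
outcome), which is why the "≥ 1 missing candidate predictor" fraction
lands at ~20.5% rather than ~60%.

**What the generator does not emulate:** pathogen aetiology, seasonality,
within-illness vital-sign trajectories, length of stay, informative
(MNAR) missingness, and the real data's tail behaviour — moment-matched
log-normals have heavier right tails than real paediatric vitals. Passing
tests on synthetic data therefore demonstrate that the *machinery* is
correct and that the *structure* of the published results (score
ordering, classification trade-offs, gains from model updating)
reproduces; they do not re-estimate the published effect sizes.

## 3. Severity scores and the threshold table

Scores use strict inequalities (a value exactly at a threshold does not
score), one point per abnormal component. Missing components contribute 0
points and clear the record's `complete_case` flag; full-case analyses
(the basis of score classification tables) subset on that flag, while
model-based analyses use imputed data.

The HR/RR thresholds are shipped as a versioned, editable YAML table
(`thresholds_v1.yaml`). The literature's "age-adjusted threshold" is not
a single number — APLS, IMCI and SIRS references differ by 10–20
beats/breaths per minute — and with the generator's moment-matched
log-normal tails the lower published cut-offs (e.g. RR > 40–50 in
infancy) would flag 40–70% of outcome-negative ARI presentations, which
no triage score intends. The version-1 defaults therefore place
tachycardia/tachypnoea cut-offs near the 97.5th centile of the
outcome-negative distributions (HR > 180/160/160, RR > 60/60/55 for
neonate/infant/child), i.e. a point flags a genuinely unusual value.
Every scored output records the table version. Directionality is
configurable: LqSOFA counts tachycardia only; mSIRS counts both
directions; mSIRS temperature uses the axillary band (> 38.0 or
< 35.5 °C) by default, the core band (> 38.5/< 36.0 °C) when core
temperatures are supplied.

Known limitation: because the three scores share one per-band threshold
table, the synthetic validation does not reproduce the *extremely* poor
specificity the original mSIRS shows with its own much lower SIRS
respiratory cut-offs; it does reproduce the discrimination ordering
(LqSOFA > qPELOD-2 > mSIRS).

## 4. Missing-data handling

**MICE.** Chained equations over the incomplete candidate predictors in a
fixed order; each variable's conditional model uses all other candidate
predictors, the outcome and age (all-observed). Continuous variables:
OLS fit with predictive mean matching, donor pool k = 5 (type-0 PMM — no
parameter draws; between-imputation variability comes from donor
sampling and chain initialisation). Binary variables: logistic fit,
Bernoulli draw from the predicted probability. Defaults m = 100 study
scale / m = 10–20 demo scale, 5–10 iterations; per-variable mean traces
are retained for convergence checks. Observed cells are never altered,
and runs are byte-reproducible for a fixed seed.

**Median-by-outcome.** For lasso updating, each missing continuous cell
receives its outcome-group median and each binary cell the group mode
(ties → 0). A single completed dataset keeps variable selection from
fragmenting across imputations.

**Pooling.** Rubin's rules: pooled estimate = mean; total variance =
mean within-variance + (1 + 1/m) × between-variance; normal-approximation
CIs. AUCs are pooled on the logit scale and back-transformed — pooling
raw AUCs can push CIs outside [0, 1].

## 5. Risk models

**Coding.** Binary signs as indicators; HR and RR continuous per 10
beats/breaths per minute; temperature (mSIRS model) as a restricted cubic
spline with 3 knots at {5th percentile, 36 °C, 95th percentile} (falling
back to {p5, median, p95} with a warning when 36 °C is outside or within
0.1 °C of the boundary knots); age in months as a main effect (needed for
the HR×age and RR×age interaction tests). Updated models add WAZ and
respiratory distress. A 13-parameter cap enforces the events-per-parameter
budget (104 events / 13 parameters = EPP 8 at study scale).

**Spline basis.** Harrell form for 3 knots: column 1 is x; column 2 is
the truncated-cubic combination normalised by (k₃−k₁)², zero below k₁
and exactly linear beyond k₃.

**Fitting.** Maximum likelihood via Newton iterations (tolerance 1e−10).
Guards: both outcome classes present, full-rank design, separation
detection (non-convergence or |coefficient| > 50) with advice to use the
ridge-penalised fallback (`ridge > 0`), which the bootstrap uses for
degenerate resamples.

**Interaction tests.** Likelihood-ratio χ² for adding one product term;
if the product adds no rank the models are identical and the test is
(0, 0, 1).

**Internal validation.** Harrell's optimism bootstrap: for each of B
resamples with replacement, refit; optimism = performance of the
resample-fit on the resample minus its performance on the original data;
adjusted = apparent − mean optimism, for both AUC and calibration slope
(the apparent slope of an MLE fit on its own training data is exactly 1,
a property of the logistic score equations that the tests pin at 1e−6).
Resamples with one outcome class or failed fits are redrawn, at most 10
consecutive times. B = 100 at study scale.

**Lasso updating.** L1-penalised logistic regression on internally
standardised columns, intercept unpenalised (after the solver runs, the
intercept is refined by solving its score equation exactly given the
slopes — stochastic-gradient solvers leave it short of optimum under
heavy penalties). The penalty λ (glmnet per-observation scale) is chosen
by 10-fold stratified cross-validated deviance; both the minimising λ and
the 1-SE λ are recorded and the 1-SE rule is the default (more
parsimonious; selection experiments show it keeps the true predictor and
zeroes noise terms reliably). λ = 0 reproduces the MLE to 1e−4; λ → ∞
leaves the intercept at logit(prevalence). Coefficients are reported on
the original scale; zeroed terms are reported as "not selected".

## 6. Evaluation

**Discrimination.** AUC as the midrank (Mann–Whitney) concordance
probability, ties counted ½; variance and 95% CI by DeLong's
placement-value method. The implementation is cross-checked in the test
suite against an O(n²) all-pairs oracle.

**Calibration.** Slope and intercept from a logistic refit of the outcome
on logit(predicted risk); decile-binned observed proportions with exact
(Clopper–Pearson) binomial CIs and rug data are exported for plotting.
Risks of exactly 0/1 are clipped to [1e−6, 1−1e−6] with a warning;
constant risk raises (slope undefined).

**Classification tables.** One row per cut-off; referral when value ≥
cut-off (scores and probability thresholds alike). Sensitivity,
specificity, NPV, PPV with Wilson CIs; likelihood ratios with log-method
CIs; referral workload columns (cases referred/community and their
percentages), the FP:TP and TN:FN ratios, and the empirical number
needed to refer (TP+FP)/TP = 1/PPV. CI methods are conventional choices
and swappable; the analysed n for score tables is the per-score full-case
n, recorded in the table attributes.

**Decision curves.** Net benefit (TP − FP·t/(1−t))/n over a default grid
of threshold probabilities 0.01–0.40 (step 0.005), against refer-all
((events − (n−events)·t/(1−t))/n, which crosses zero exactly at
t = prevalence) and refer-none (identically 0). Referral at exactly
risk = t counts as referral. Curves are not smoothed. The threshold also
encodes the exchange rate: at t = 5%, one correct referral is worth 19
incorrect ones, NNR = 1/t = 20.

## 7. Pipeline

Stages: simulate/load → scenario filters → stratified descriptive
summary (median/IQR with rank-sum p for continuous; n/N(%) with χ², or
Fisher's exact when any expected cell < 5, for binary) → score
validation (full-case) → MICE → score-component models (pooled AUC over
imputations on the logit scale; bootstrap optimism on the first completed
dataset — per-imputation bootstrap is available through the library but
is not the default path, for runtime) → median-by-outcome completion →
lasso-updated models → probability-threshold classification → decision
curves → JSON report with a provenance block (config digest, seed,
package and threshold-table versions). Identical config + seed give an
identical report.

Scenario flags (independent, composable): `exclude_baseline_hypoxaemia`
drops presentations with observed SpO₂ < 90 (records with missing SpO₂
are retained); `one_visit_per_child` keeps one random presentation per
child (a clustering check standing in for random effects, which the
repeat-visit structure — 22% single presenters — makes hard to fit);
`reclassify_community_oxygen` flips a stated count or explicit list of
community-managed outcome-negative presentations to outcome-positive.

**Problem sizes.** The default pipeline profile uses m = 20 imputations
and B = 20 bootstrap resamples; `scripts/acceptance.py` uses m = 10 and
B = 100; the study-scale settings are m = 100, B = 100 and are plain
config changes. Simulation-based tests use 500–20 000 observations and
20 replicates per experiment, sizes at which the checked properties
(null optimism ≈ 0.5, CI coverage ≥ 90%, selection consistency) are
comfortably identifiable.

## 8. Numerical notes and edge cases

- Visit-count calibration and the SpO₂ beta concentration are solved
  with root finders; the beta IQR is not monotone in concentration for
  very skewed shapes, so a sign change is bracketed on a log grid first
  and the high-concentration root preferred.
- Intercept calibration in score-linked mode: bisection over [−40, 40]
  on the logit scale.
- `knot_locations` requires ≥ 20 observed temperatures and raises on
  degenerate (near-constant) distributions.
- LOWESS exploration requires ≥ 50 points and non-constant x; bandwidth
  1.0 approaches a global linear fit.
- All stochastic components (generator, missingness, MICE, bootstrap,
  CV folds, saga solver) are seeded; the saga shuffle is pinned.

## 9. Known limitations

- Synthetic marginals are moment-matched to published medians/IQRs but
  tail shapes, between-vital correlations (beyond the shared outcome and
  child effects) and MNAR mechanisms are not represented.
- Type-0 PMM understates imputation-parameter uncertainty slightly;
  Rubin intervals are, if anything, a little narrow.
- The shared per-band threshold table cannot express score-specific
  thresholds (see §3 on mSIRS).
- No mixed-effects models; clustering is addressed only through the
  one-visit-per-child sensitivity analysis.
- No recalibration methods for transporting a fitted model to a new
  population.
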