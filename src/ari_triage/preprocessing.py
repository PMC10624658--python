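"""Eligibility, measurement-conversion and anthropometric-window rules.

Covers the study-entry and data-preparation steps that precede scoring:

* ARI eligibility from a symptom profile (criterion A: at least one
  qualifying respiratory symptom or sign; criterion B, applied only to
  children sent home directly: a compatible syndromic diagnosis).
* Rectal-to-axillary temperature conversion (subtract 0.5 degrees C).
* Selection of the anthropometric measurement closest to an illness visit
  within a per-kind window (height <= 28 days; MUAC <= 28 days and weight
  <= 14 days, both additionally requiring no intervening admission).
* Age-adjusted z-scores via the LMS (lambda-mu-sigma) transform against a
  growth reference table.  A coarse toy reference ships with the package;
  real reference tables are a drop-in CSV with the same schema
  (``kind,sex,age_months,L,M,S``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import date, timedelta
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SymptomProfile",
    "AnthropometricMeasurement",
    "LMSReference",
    "assign_age_band",
    "filter_ari",
    "rectal_to_axillary",
    "select_anthropometry",
    "zscore",
    "ANTHRO_WINDOWS_DAYS",
    "QUALIFYING_SYMPTOMS",
    "COMPATIBLE_DIAGNOSES",
]

QUALIFYING_SYMPTOMS = (
    "rhinorrhoea",
    "nasal_congestion",
    "cough",
    "chest_indrawing",
    "nasal_flaring",
    "grunting",
    "tracheal_tug",
    "head_bobbing",
    "stridor",
    "crepitations",
    "wheeze",
)

COMPATIBLE_DIAGNOSES = frozenset(
    {
        "rhinitis",
        "croup",
        "bronchiolitis",
        "influenza-like illness",
        "pneumonia",
        "viral infection",
        "wheeze",
    }
)

RESP_DISTRESS_COMPONENTS = (
    "chest_indrawing",
    "nasal_flaring",
    "grunting",
    "tracheal_tug",
    "head_bobbing",
)

#: Per-kind selection window in days; MUAC and weight additionally require
#: no admission between measurement and visit.
ANTHRO_WINDOWS_DAYS = {"height": 28, "muac": 28, "weight": 14}
_NEEDS_NO_ADMISSION = {"muac", "weight"}


def assign_age_band(age_months) -> np.ndarray | str:
    """Age band: neonate < 1 month, infant 1 to < 12 months, child 12-24.

    The study tabulates vitals this way without printing the cut points;
    these bounds are the conventional paediatric ones and are the single
    definition used throughout the package.
    """
    scalar = np.isscalar(age_months)
    a = np.atleast_1d(np.asarray(age_months, dtype=float))
    if (a < 0).any():
        raise ValueError("age_months must be non-negative")
    out = np.where(a < 1.0, "neonate", np.where(a < 12.0, "infant", "child"))
    return out[0] if scalar else out


@dataclass
class SymptomProfile:
    """Presenting symptoms/signs and syndromic diagnoses for one visit."""

    rhinorrhoea: bool = False
    nasal_congestion: bool = False
    cough: bool = False
    chest_indrawing: bool = False
    nasal_flaring: bool = False
    grunting: bool = False
    tracheal_tug: bool = False
    head_bobbing: bool = False
    stridor: bool = False
    crepitations: bool = False
    wheeze: bool = False
    syndromic_diagnosis: frozenset = frozenset()
    sent_home_directly: bool = False

    @property
    def resp_distress(self) -> bool:
        """Composite: any of chest indrawing, nasal flaring, grunting,
        tracheal tug, head bobbing."""
        return any(getattr(self, c) for c in RESP_DISTRESS_COMPONENTS)


def filter_ari(profile: SymptomProfile) -> bool:
    """ARI eligibility.

    Criterion A: at least one qualifying symptom/sign (rhinorrhoea, nasal
    congestion, cough, any respiratory-distress component, stridor,
    crepitations or wheeze).  Criterion B, required only when the child was
    sent home directly from the clinic: at least one compatible syndromic
    diagnosis.  An empty diagnosis set with ``sent_home_directly`` fails B.
    """
    criterion_a = any(getattr(profile, s) for s in QUALIFYING_SYMPTOMS)
    if not criterion_a:
        return False
    if profile.sent_home_directly:
        diagnoses = {d.lower() for d in profile.syndromic_diagnosis}
        return bool(diagnoses & COMPATIBLE_DIAGNOSES)
    return True


def rectal_to_axillary(temp_rectal: float) -> float:
    """Convert a rectal (core) temperature to axillary by subtracting 0.5 C.

    Raises ``ValueError`` outside the plausible physiologic range 30-43 C.
    """
    t = float(temp_rectal)
    if not 30.0 <= t <= 43.0:
        raise ValueError(
            f"rectal temperature {t} degrees C outside plausible range [30, 43]"
        )
    return t - 0.5


@dataclass(frozen=True)
class AnthropometricMeasurement:
    """One anthropometric measurement: weight (kg), height (cm) or MUAC (cm)."""

    child_id: str
    measure_date: date
    kind: str
    value: float

    def __post_init__(self) -> None:
        if self.kind not in ANTHRO_WINDOWS_DAYS:
            raise ValueError(f"unknown measurement kind {self.kind!r}")
        if self.value <= 0:
            raise ValueError("measurement value must be positive")


def _admission_intervenes(
    measure_date: date, visit_date: date, admission_intervals: Iterable[tuple[date, date]]
) -> bool:
    """True if any admission interval overlaps the open interval strictly
    between measurement and visit dates."""
    lo, hi = min(measure_date, visit_date), max(measure_date, visit_date)
    if (hi - lo).days <= 1:
        return False  # no dates strictly between
    open_lo, open_hi = lo + timedelta(days=1), hi - timedelta(days=1)
    for start, end in admission_intervals:
        if start <= open_hi and end >= open_lo:
            return True
    return False


def select_anthropometry(
    visit_date: date,
    measurements: Sequence[AnthropometricMeasurement],
    admission_intervals: Sequence[tuple[date, date]] = (),
    allow_after_visit: bool = True,
) -> dict[str, tuple[float, int] | None]:
    """Pick, per kind, the measurement nearest the visit that satisfies the
    window rules.

    Windows are inclusive (``height``/``muac`` <= 28 days, ``weight`` <= 14
    days); MUAC and weight additionally require no admission interval
    overlapping the open date range strictly between measurement and visit.
    Ties in absolute distance break toward the earlier measurement.  By
    default measurements after the visit qualify if within the window; set
    ``allow_after_visit=False`` to restrict to prior measurements.

    Returns ``{kind: (value, interval_days) or None}`` for the three kinds.
    """
    chosen: dict[str, tuple[float, int] | None] = {k: None for k in ANTHRO_WINDOWS_DAYS}
    best_key: dict[str, tuple[int, date]] = {}
    for m in measurements:
        delta = (m.measure_date - visit_date).days
        if not allow_after_visit and delta > 0:
            continue
        if abs(delta) > ANTHRO_WINDOWS_DAYS[m.kind]:
            continue
        if m.kind in _NEEDS_NO_ADMISSION and _admission_intervenes(
            m.measure_date, visit_date, admission_intervals
        ):
            continue
        key = (abs(delta), m.measure_date)
        if m.kind not in best_key or key < best_key[m.kind]:
            best_key[m.kind] = key
            chosen[m.kind] = (m.value, abs(delta))
    return chosen


class LMSReference:
    """A growth reference as LMS parameters on a (kind, sex, age) grid,
    linearly interpolated in age."""

    def __init__(self, table: pd.DataFrame):
        required = {"kind", "sex", "age_months", "L", "M", "S"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"LMS table missing columns: {sorted(missing)}")
        if (table["M"] <= 0).any() or (table["S"] <= 0).any():
            raise ValueError("LMS M and S must be positive")
        self.table = table.sort_values(["kind", "sex", "age_months"]).reset_index(drop=True)

    @classmethod
    def from_csv(cls, path) -> "LMSReference":
        return cls(pd.read_csv(path, comment="#"))

    @classmethod
    def toy(cls) -> "LMSReference":
        """The bundled coarse toy reference (synthetic; testing/demo only)."""
        with resources.files("ari_triage.data").joinpath("lms_toy.csv").open() as fh:
            return cls(pd.read_csv(fh, comment="#"))

    def lms_at(self, kind: str, sex: str, age_months: float) -> tuple[float, float, float] | None:
        sub = self.table[(self.table["kind"] == kind) & (self.table["sex"] == sex)]
        if sub.empty:
            return None
        ages = sub["age_months"].to_numpy(dtype=float)
        if not ages[0] <= age_months <= ages[-1]:
            return None
        L = float(np.interp(age_months, ages, sub["L"]))
        M = float(np.interp(age_months, ages, sub["M"]))
        S = float(np.interp(age_months, ages, sub["S"]))
        return L, M, S


def zscore(
    kind: str,
    value: float,
    age_months: float,
    sex: str,
    reference: LMSReference,
) -> float:
    """Age- and sex-adjusted z-score via the LMS transform.

    ``z = ((value/M)**L - 1) / (L*S)`` for ``L != 0`` and
    ``z = ln(value/M) / S`` for ``L == 0``.  Returns NaN (with a warning)
    when the reference does not cover (kind, sex, age).
    """
    if value <= 0:
        raise ValueError("measurement value must be positive")
    lms = reference.lms_at(kind, sex, age_months)
    if lms is None:
        warnings.warn(
            f"no LMS reference for kind={kind!r}, sex={sex!r}, age={age_months}; "
            "returning missing",
            stacklevel=2,
        )
        return float("nan")
    L, M, S = lms
    if abs(L) < 1e-12:
        return float(np.log(value / M) / S)
    return float(((value / M) ** L - 1.0) / (L * S))
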