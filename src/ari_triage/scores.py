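"""Points-based paediatric severity scores: LqSOFA, adapted qPELOD-2, mSIRS.

Each score allocates one point per abnormal component:

* **LqSOFA** (0-4): prolonged capillary refill (> 2 s), not alert on the
  AVPU scale, age-adjusted tachycardia, age-adjusted tachypnoea.
* **qPELOD-2, adapted** (0-3): not alert on AVPU, age-adjusted tachycardia,
  prolonged capillary refill (the adaptation replaces blood pressure with
  capillary refill and the Glasgow Coma Scale with AVPU).
* **mSIRS** (0-3): temperature outside its band, heart rate outside the
  age-adjusted range (tachy- OR bradycardia), age-adjusted tachypnoea.

Thresholds live in an editable YAML table (:class:`ThresholdTable`); every
reported result should name the table version used.  Comparisons are strict
inequalities: a value exactly at a threshold does not score.

Missing components contribute zero points and clear the record's
``complete_case`` flag, so that full-case analyses can be restricted
downstream without re-deriving missingness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ThresholdTable",
    "ScoreResult",
    "lqsofa",
    "qpelod2_adapted",
    "msirs",
    "score_table",
    "SCORE_NAMES",
]

SCORE_NAMES = ("lqsofa", "qpelod2", "msirs")

AGE_BANDS = ("neonate", "infant", "child")

_COMPONENTS = {
    "lqsofa": ("crt_prolonged", "avpu_not_alert", "tachycardia", "tachypnoea"),
    "qpelod2": ("avpu_not_alert", "tachycardia", "crt_prolonged"),
    "msirs": ("temperature", "heart_rate", "tachypnoea"),
}

SCORE_MAX = {"lqsofa": 4, "qpelod2": 3, "msirs": 3}


@dataclass
class ThresholdTable:
    """Per-age-band vital-sign cut-offs and score directionality flags.

    ``age_bands`` maps band name -> ``{hr_upper, hr_lower, rr_upper}``
    (beats/breaths per minute); ``temperature`` maps measurement site
    (``core``/``axillary``) -> ``{temp_upper, temp_lower}`` in degrees C.
    """

    age_bands: Mapping[str, Mapping[str, float]]
    temperature: Mapping[str, Mapping[str, float]]
    crt_cutoff_seconds: float = 2.0
    directionality: Mapping[str, bool] = field(
        default_factory=lambda: {"lqsofa_bradycardia": False, "msirs_bradycardia": True}
    )
    version: int | str = "unversioned"

    def __post_init__(self) -> None:
        for band, vals in self.age_bands.items():
            if band not in AGE_BANDS:
                raise ValueError(f"unknown age band {band!r}")
            if not vals["hr_lower"] < vals["hr_upper"]:
                raise ValueError(f"{band}: hr_lower must be < hr_upper")
            if min(vals["hr_lower"], vals["hr_upper"], vals["rr_upper"]) <= 0:
                raise ValueError(f"{band}: thresholds must be positive")
        for site, vals in self.temperature.items():
            if not vals["temp_lower"] < vals["temp_upper"]:
                raise ValueError(f"{site}: temp_lower must be < temp_upper")
        if self.crt_cutoff_seconds <= 0:
            raise ValueError("crt_cutoff_seconds must be positive")

    # -- serialisation ---------------------------------------------------
    @classmethod
    def default(cls) -> "ThresholdTable":
        """The bundled version-1 table (APLS-style HR/RR ranges)."""
        with resources.files("ari_triage.data").joinpath("thresholds_v1.yaml").open() as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def from_dict(cls, d: Mapping) -> "ThresholdTable":
        return cls(
            age_bands=d["age_bands"],
            temperature=d["temperature"],
            crt_cutoff_seconds=float(d.get("crt_cutoff_seconds", 2.0)),
            directionality=d.get(
                "directionality",
                {"lqsofa_bradycardia": False, "msirs_bradycardia": True},
            ),
            version=d.get("version", "unversioned"),
        )

    @classmethod
    def from_yaml(cls, path) -> "ThresholdTable":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "age_bands": {b: dict(v) for b, v in self.age_bands.items()},
            "temperature": {s: dict(v) for s, v in self.temperature.items()},
            "crt_cutoff_seconds": self.crt_cutoff_seconds,
            "directionality": dict(self.directionality),
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def band_lookup(self, key: str) -> dict[str, float]:
        """Threshold value per band as a dict band -> value."""
        return {b: self.age_bands[b][key] for b in self.age_bands}


@dataclass
class ScoreResult:
    """One score evaluated on one presentation."""

    score_name: str
    points: int
    components: dict[str, int | None]
    complete_case: bool

    def __post_init__(self) -> None:
        assert self.points == sum(v for v in self.components.values() if v is not None)


def _as_float(x) -> float:
    return np.nan if x is None or (isinstance(x, float) and np.isnan(x)) else float(x)


def _binary_component(value) -> int | None:
    if value is None:
        return None
    v = _as_float(value)
    if np.isnan(v):
        return None
    return int(v != 0)


def _gt(value, threshold) -> int | None:
    v = _as_float(value)
    if np.isnan(v):
        return None
    return int(v > threshold)


def _lt(value, threshold) -> int | None:
    v = _as_float(value)
    if np.isnan(v):
        return None
    return int(v < threshold)


def _outside(value, lower, upper) -> int | None:
    v = _as_float(value)
    if np.isnan(v):
        return None
    return int(v > upper or v < lower)


def _band_thresholds(record, thresholds: ThresholdTable) -> Mapping[str, float]:
    band = record["age_band"]
    try:
        return thresholds.age_bands[band]
    except KeyError:
        raise KeyError(f"age_band {band!r} not in threshold table") from None


def _result(name: str, components: dict[str, int | None]) -> ScoreResult:
    points = sum(v for v in components.values() if v is not None)
    complete = all(v is not None for v in components.values())
    return ScoreResult(name, points, components, complete)


def lqsofa(record, thresholds: ThresholdTable | None = None) -> ScoreResult:
    """LqSOFA score (0-4) for a single presentation record.

    One point each for capillary refill > 2 s, AVPU below alert, heart rate
    above the age-adjusted threshold, and respiratory rate above the
    age-adjusted threshold.  With ``lqsofa_bradycardia`` enabled in the
    threshold table, heart rate below the lower bound also scores.
    """
    thresholds = thresholds or ThresholdTable.default()
    t = _band_thresholds(record, thresholds)
    if thresholds.directionality.get("lqsofa_bradycardia", False):
        hr = _outside(record.get("heart_rate"), t["hr_lower"], t["hr_upper"])
    else:
        hr = _gt(record.get("heart_rate"), t["hr_upper"])
    components = {
        "crt_prolonged": _binary_component(record.get("crt_prolonged")),
        "avpu_not_alert": _binary_component(record.get("avpu_not_alert")),
        "tachycardia": hr,
        "tachypnoea": _gt(record.get("resp_rate"), t["rr_upper"]),
    }
    return _result("lqsofa", components)


def qpelod2_adapted(record, thresholds: ThresholdTable | None = None) -> ScoreResult:
    """Adapted qPELOD-2 score (0-3): AVPU below alert, age-adjusted
    tachycardia, capillary refill > 2 s."""
    thresholds = thresholds or ThresholdTable.default()
    t = _band_thresholds(record, thresholds)
    components = {
        "avpu_not_alert": _binary_component(record.get("avpu_not_alert")),
        "tachycardia": _gt(record.get("heart_rate"), t["hr_upper"]),
        "crt_prolonged": _binary_component(record.get("crt_prolonged")),
    }
    return _result("qpelod2", components)


def msirs(
    record,
    thresholds: ThresholdTable | None = None,
    temp_site: str = "axillary",
) -> ScoreResult:
    """mSIRS score (0-3): temperature outside its band, heart rate outside
    the age-adjusted range (both directions by default), age-adjusted
    tachypnoea.

    ``temp_site`` selects the temperature band; the default ``axillary``
    band (> 38.0 or < 35.5 degrees C) is the study adaptation of the core
    band (> 38.5 or < 36.0 degrees C).
    """
    thresholds = thresholds or ThresholdTable.default()
    t = _band_thresholds(record, thresholds)
    temp_band = thresholds.temperature[temp_site]
    if thresholds.directionality.get("msirs_bradycardia", True):
        hr = _outside(record.get("heart_rate"), t["hr_lower"], t["hr_upper"])
    else:
        hr = _gt(record.get("heart_rate"), t["hr_upper"])
    components = {
        "temperature": _outside(
            record.get("temp_axillary"), temp_band["temp_lower"], temp_band["temp_upper"]
        ),
        "heart_rate": hr,
        "tachypnoea": _gt(record.get("resp_rate"), t["rr_upper"]),
    }
    return _result("msirs", components)


def _map_band(series: pd.Series, lookup: Mapping[str, float]) -> pd.Series:
    return series.map(lookup).astype(float)


def score_table(
    records: pd.DataFrame,
    thresholds: ThresholdTable | None = None,
    temp_site: str = "axillary",
) -> pd.DataFrame:
    """Vectorised scoring of a presentation table.

    Returns a DataFrame indexed like ``records`` with, per score,
    ``<score>`` (points) and ``<score>_complete`` (all components observed).
    ``result.attrs["complete_case_counts"]`` holds the per-score full-case
    counts used by downstream full-case analyses; ``attrs["threshold_version"]``
    records the table version.
    """
    thresholds = thresholds or ThresholdTable.default()
    out = pd.DataFrame(index=records.index)
    if len(records) == 0:
        for s in SCORE_NAMES:
            out[s] = pd.Series(dtype=int)
            out[f"{s}_complete"] = pd.Series(dtype=bool)
        out.attrs["complete_case_counts"] = {s: 0 for s in SCORE_NAMES}
        out.attrs["threshold_version"] = thresholds.version
        return out

    hr = records["heart_rate"].astype(float)
    rr = records["resp_rate"].astype(float)
    temp = records["temp_axillary"].astype(float)
    crt = records["crt_prolonged"].astype(float)
    avpu = records["avpu_not_alert"].astype(float)

    hr_up = _map_band(records["age_band"], thresholds.band_lookup("hr_upper"))
    hr_lo = _map_band(records["age_band"], thresholds.band_lookup("hr_lower"))
    rr_up = _map_band(records["age_band"], thresholds.band_lookup("rr_upper"))
    tband = thresholds.temperature[temp_site]

    def nan_indicator(cond: pd.Series, source: pd.Series) -> pd.Series:
        ind = cond.astype(float)
        ind[source.isna()] = np.nan
        return ind

    tachy = nan_indicator(hr > hr_up, hr)
    hr_both = nan_indicator((hr > hr_up) | (hr < hr_lo), hr)
    tachyp = nan_indicator(rr > rr_up, rr)
    temp_abn = nan_indicator((temp > tband["temp_upper"]) | (temp < tband["temp_lower"]), temp)
    crt_i = nan_indicator(crt != 0, crt)
    avpu_i = nan_indicator(avpu != 0, avpu)

    lq_hr = hr_both if thresholds.directionality.get("lqsofa_bradycardia", False) else tachy
    ms_hr = hr_both if thresholds.directionality.get("msirs_bradycardia", True) else tachy

    comps = {
        "lqsofa": [crt_i, avpu_i, lq_hr, tachyp],
        "qpelod2": [avpu_i, tachy, crt_i],
        "msirs": [temp_abn, ms_hr, tachyp],
    }
    counts = {}
    for name, cols in comps.items():
        stacked = pd.concat(cols, axis=1)
        out[name] = stacked.sum(axis=1, skipna=True).astype(int)
        out[f"{name}_complete"] = stacked.notna().all(axis=1)
        counts[name] = int(out[f"{name}_complete"].sum())
    out.attrs["complete_case_counts"] = counts
    out.attrs["threshold_version"] = thresholds.version
    return out
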