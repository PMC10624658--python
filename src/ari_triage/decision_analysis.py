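"""Decision curve analysis: net benefit and number-needed-to-refer.

At a threshold probability ``t``, referring when predicted risk >= t has

    net benefit = (TP - FP * t / (1 - t)) / n

in units of true referrals per presentation.  The comparators are
refer-all (net benefit ``(events - (n - events) * t/(1-t)) / n``, crossing
zero exactly at t = prevalence) and refer-none (identically zero).  The
threshold also encodes an exchange rate: at t, one correct referral is
worth ``(1-t)/t`` incorrect ones, i.e. a number needed to refer of ``1/t``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "net_benefit",
    "decision_curve",
    "DecisionCurve",
    "nnr_from_threshold",
    "default_threshold_grid",
]


def _check_threshold(t: float) -> float:
    t = float(t)
    if not 0.0 < t < 1.0:
        raise ValueError(f"threshold probability must lie strictly in (0, 1), got {t}")
    return t


def net_benefit(risk, outcome, t: float) -> float:
    """Net benefit of the rule "refer when risk >= t" at threshold ``t``."""
    t = _check_threshold(t)
    r = np.asarray(risk, dtype=float)
    y = np.asarray(outcome, dtype=float)
    n = len(y)
    referred = r >= t
    tp = float(((referred) & (y == 1)).sum())
    fp = float(((referred) & (y == 0)).sum())
    return (tp - fp * t / (1 - t)) / n


def nnr_from_threshold(t: float) -> tuple[float, float]:
    """Number needed to refer implied by a threshold probability.

    Returns ``(nnr, exchange_rate)`` where ``nnr = 1/t`` (children referred
    per true case at the margin) and ``exchange_rate = (1-t)/t`` (incorrect
    referrals judged equivalent to one correct referral).
    """
    t = _check_threshold(t)
    return 1.0 / t, (1.0 - t) / t


def default_threshold_grid(start: float = 0.01, stop: float = 0.40, step: float = 0.005) -> np.ndarray:
    """The default evaluation grid of threshold probabilities (1-40%)."""
    n = int(round((stop - start) / step))
    return start + step * np.arange(n + 1)


@dataclass
class DecisionCurve:
    """Net benefit of a model against refer-all and refer-none over a
    threshold grid."""

    thresholds: np.ndarray
    nb_model: np.ndarray
    nb_all: np.ndarray
    nb_none: np.ndarray
    n: int
    events: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "nb_model": self.nb_model,
                "nb_all": self.nb_all,
                "nb_none": self.nb_none,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def decision_curve(risk, outcome, grid=None) -> DecisionCurve:
    """Decision curve over a threshold grid (default 0.01-0.40 by 0.005).

    Duplicate grid entries are deduplicated with a warning; each grid value
    must lie strictly in (0, 1).
    """
    if grid is None:
        grid = default_threshold_grid()
    grid = np.asarray(grid, dtype=float)
    uniq = np.unique(grid)
    if len(uniq) < len(grid):
        warnings.warn("duplicate thresholds in grid deduplicated", stacklevel=2)
    for t in uniq:
        _check_threshold(t)
    y = np.asarray(outcome, dtype=float)
    n = len(y)
    events = int(y.sum())
    nb_model = np.array([net_benefit(risk, y, t) for t in uniq])
    nb_all = (events - (n - events) * uniq / (1 - uniq)) / n
    return DecisionCurve(
        thresholds=uniq,
        nb_model=nb_model,
        nb_all=nb_all,
        nb_none=np.zeros_like(uniq),
        n=n,
        events=events,
    )
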