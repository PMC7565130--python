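"""Cutoff-based prediction of pathologic response from MTVcsc.

The response cutoff is derived from the highest MTVcsc observed in the
pathologic-complete-response (pCR) group, optionally rounded up to the next
0.05 cm^3 step (1.7 cm^3 observed maximum -> 1.75 cm^3 cutoff).  Prediction
is strict: MTVcsc < cutoff predicts pCR, values at or above the cutoff
predict residual tumor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_CUTOFF",
    "ResponsePrediction",
    "ConfusionTable",
    "AccuracyResult",
    "classify",
    "derive_cutoff",
    "accuracy",
    "confusion_from_cohort",
    "accuracy_by_group",
]

DEFAULT_CUTOFF = 1.75  # cm^3


@dataclass(frozen=True)
class ResponsePrediction:
    patient_id: str
    mtv_csc: float
    predicted_pcr: bool
    cutoff_used: float

    def __post_init__(self) -> None:
        if self.predicted_pcr != (self.mtv_csc < self.cutoff_used):
            raise ValueError("prediction inconsistent with cutoff rule")


@dataclass(frozen=True)
class ConfusionTable:
    """Counts of responders/non-responders below and above the cutoff.

    a: responders (pCR) below cutoff      b: non-responders below cutoff
    c: responders above cutoff            d: non-responders above cutoff
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            if getattr(self, name) < 0:
                raise ValueError(f"cell {name} must be nonnegative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class AccuracyResult:
    correct: int
    total: int

    @property
    def percent(self) -> float:
        return 100.0 * self.correct / self.total

    @property
    def rounded(self) -> int:
        return int(round(self.percent))

    def __str__(self) -> str:
        return f"{self.rounded}% ({self.correct}/{self.total})"


def classify(mtv_csc: float, cutoff: float = DEFAULT_CUTOFF) -> bool:
    """True (predicted pCR) iff ``mtv_csc`` < ``cutoff`` (strict)."""
    if not mtv_csc > 0:
        raise ValueError(f"MTVcsc must be positive, got {mtv_csc}")
    return mtv_csc < cutoff


def derive_cutoff(pcr_group_mtvcsc, round_up_step: float | None = 0.05) -> float:
    """Cutoff = highest MTVcsc in the pCR group, rounded up to the next step.

    With the default 0.05 cm^3 step, an observed maximum of 1.7 yields 1.75;
    pass ``round_up_step=None`` for the raw maximum.
    """
    values = list(pcr_group_mtvcsc)
    if not values:
        raise ValueError("pCR group is empty; no cutoff can be derived")
    top = float(max(values))
    if round_up_step is None:
        return top
    s = float(round_up_step)
    n = math.floor(top / s + 1e-9)
    if abs(n * s - top) < 1e-9:  # already on the grid: step strictly above
        return (n + 1) * s
    return math.ceil(top / s - 1e-9) * s


def accuracy(tab: ConfusionTable) -> AccuracyResult:
    """Prediction accuracy 100*(a+d)/total: below-cutoff pCR and
    above-cutoff residual tumors are the correct calls."""
    if tab.total == 0:
        raise ValueError("confusion table is empty")
    return AccuracyResult(correct=tab.a + tab.d, total=tab.total)


def confusion_from_cohort(
    mtv_csc: np.ndarray, pcr: np.ndarray, cutoff: float = DEFAULT_CUTOFF
) -> ConfusionTable:
    mtv_csc = np.asarray(mtv_csc, dtype=float)
    pcr = np.asarray(pcr, dtype=bool)
    below = mtv_csc < cutoff
    return ConfusionTable(
        a=int(np.sum(below & pcr)),
        b=int(np.sum(below & ~pcr)),
        c=int(np.sum(~below & pcr)),
        d=int(np.sum(~below & ~pcr)),
    )


def accuracy_by_group(
    cohort: pd.DataFrame,
    group_col: str,
    cutoff: float = DEFAULT_CUTOFF,
    mtv_col: str = "mtv_csc",
    pcr_col: str = "pcr",
) -> pd.DataFrame:
    """Table-style confusion counts and accuracy per level of ``group_col``."""
    rows = []
    for level, sub in cohort.groupby(group_col, sort=True):
        tab = confusion_from_cohort(sub[mtv_col].to_numpy(), sub[pcr_col].to_numpy(), cutoff)
        acc = accuracy(tab)
        rows.append(
            {
                group_col: level,
                "pcr_below": tab.a,
                "residual_below": tab.b,
                "pcr_above": tab.c,
                "residual_above": tab.d,
                "n": tab.total,
                "accuracy_pct": acc.percent,
                "accuracy": str(acc),
            }
        )
    return pd.DataFrame(rows)
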