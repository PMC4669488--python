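"""Prediction accuracy: average fold-error (AFE) against literature clearances.

A predicted hepatic clearance is scored against N independent literature
reports of the observed in vivo clearance:

    AFE = 10 ^ [ (1/N) Σ_i log10(predicted / observed_i) ]

i.e. the predicted value divided by the geometric mean of the observations.
AFE = 1 is perfect; the conventional two-fold precision window is
0.5 ≤ AFE ≤ 2 (inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .activity import summarize_activity

__all__ = [
    "ObservedClearance",
    "ObservedClearanceSet",
    "AccuracyReport",
    "afe",
    "accuracy_summary",
]


@dataclass(frozen=True)
class ObservedClearance:
    """One literature report of in vivo clearance (mL/min/kg); SD optional."""

    label: str
    clh_obs: float
    sd: Optional[float] = None
    n_subjects: Optional[int] = None

    def __post_init__(self):
        if self.clh_obs <= 0:
            raise ValueError(f"{self.label}: observed clearance must be positive")


@dataclass(frozen=True)
class ObservedClearanceSet:
    entries: tuple[ObservedClearance, ...]

    def __post_init__(self):
        if len(self.entries) < 1:
            raise ValueError("need at least one observed clearance report")

    @property
    def n(self) -> int:
        return len(self.entries)

    @property
    def values(self) -> np.ndarray:
        return np.array([e.clh_obs for e in self.entries])

    @property
    def geometric_mean(self) -> float:
        return float(np.exp(np.mean(np.log(self.values))))


@dataclass(frozen=True)
class AccuracyReport:
    """Cohort-level AFE summary for one prediction method."""

    per_donor: pd.DataFrame  # donor_id, afe
    mean: float
    sd: float
    min: float
    max: float
    p2_5: float
    p97_5: float
    pct_within_2fold: float  # percent of donors with 0.5 <= AFE <= 2


def afe(predicted: float, observed: ObservedClearanceSet) -> float:
    """Average fold-error of one predicted clearance against all N reports."""
    if predicted <= 0:
        raise ValueError(f"predicted clearance must be positive, got {predicted}")
    return float(10 ** np.mean(np.log10(predicted / observed.values)))


def accuracy_summary(
    per_donor_predictions,
    observed: ObservedClearanceSet,
    donor_ids: Optional[Sequence[str]] = None,
) -> AccuracyReport:
    """Per-donor AFE values and their population summary.

    ``per_donor_predictions`` is an array of predicted CL_H (mL/min/kg), one
    per donor (a single-value sequence degenerates to one pooled AFE, as for
    an all-means prediction method).
    """
    preds = np.asarray(per_donor_predictions, dtype=float)
    if preds.size == 0:
        raise ValueError("need at least one prediction")
    if np.any(preds <= 0):
        raise ValueError("all predicted clearances must be positive")
    gm = observed.geometric_mean
    afes = preds / gm
    ids = list(donor_ids) if donor_ids is not None else [f"donor{i}" for i in range(preds.size)]
    if len(ids) != preds.size:
        raise ValueError("donor_ids must align with predictions")
    s = summarize_activity(afes)
    within = (afes >= 0.5) & (afes <= 2.0)
    return AccuracyReport(
        per_donor=pd.DataFrame({"donor_id": ids, "afe": afes}),
        mean=s.mean,
        sd=s.sd,
        min=s.min,
        max=s.max,
        p2_5=s.p2_5,
        p97_5=s.p97_5,
        pct_within_2fold=float(100.0 * within.mean()),
    )
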