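"""Outcome metrics of a simulated MIPD trial.

Three per-patient metrics summarise a trial: the maintenance INR (measured on
the last trial day — success means it falls inside the therapeutic range),
the peak INR (largest measurement, a bleeding-risk proxy) and the TTR (the
fraction of INR measurements inside the therapeutic range).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import TrialDataset


@dataclass(frozen=True)
class TherapeuticRange:
    low: float = 2.0
    high: float = 3.0
    target: float = 2.5

    def __post_init__(self):
        if not self.low < self.target < self.high:
            raise ValueError("require low < target < high")

    def contains(self, inr) -> np.ndarray:
        inr = np.asarray(inr)
        return (inr >= self.low) & (inr <= self.high)


@dataclass
class TrialOutcome:
    per_patient: pd.DataFrame   # ID, MaintenanceINR, PeakINR, TTR, Success
    success_rate: float

    @property
    def median_ttr(self) -> float:
        return float(self.per_patient["TTR"].median())


def ttr(inr_series, therapeutic_range: TherapeuticRange) -> float:
    """Fraction of measurements inside the therapeutic range."""
    inr_series = np.asarray(inr_series, dtype=float)
    if inr_series.size == 0:
        raise ValueError("INR series must be non-empty")
    return float(therapeutic_range.contains(inr_series).mean())


def summarise_trial(dataset: TrialDataset,
                    therapeutic_range: TherapeuticRange) -> TrialOutcome:
    """Per-patient metrics plus the cohort success rate.

    Patients without any INR measurement are excluded with a warning.
    """
    inr = dataset.measurements[dataset.measurements["Observable"] == "INR"]
    rows = []
    for pid in dataset.covariates["ID"]:
        series = inr[inr["ID"] == pid].sort_values("Time_h")["Value"].values
        if series.size == 0:
            warnings.warn(f"patient {pid} has no INR measurements; excluded",
                          stacklevel=2)
            continue
        maintenance = float(series[-1])
        rows.append({
            "ID": pid,
            "MaintenanceINR": maintenance,
            "PeakINR": float(series.max()),
            "TTR": ttr(series, therapeutic_range),
            "Success": bool(therapeutic_range.contains(maintenance)),
        })
    if not rows:
        raise ValueError("no patient with INR measurements in the dataset")
    table = pd.DataFrame(rows)
    return TrialOutcome(per_patient=table,
                        success_rate=float(table["Success"].mean()))
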