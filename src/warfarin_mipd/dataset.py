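"""Tidy trial datasets and their on-disk representation.

A :class:`TrialDataset` bundles three tables with fixed column orders:

* ``covariates``: ID, CYP2C9, VKORC1, Age
* ``measurements``: ID, Observable, Time_h, Value
* ``doses``: ID, Time_h, Dose_mg

plus a metadata mapping (trial name, seed, config hash, stopped patients).
``write_dataset`` lays these out as three CSV files and a JSON sidecar in a
directory; ``read_dataset`` validates the schema on the way back in.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

OBSERVABLES = ("warfarin_conc_mg_per_L", "INR")

_SCHEMAS = {
    "covariates": ["ID", "CYP2C9", "VKORC1", "Age"],
    "measurements": ["ID", "Observable", "Time_h", "Value"],
    "doses": ["ID", "Time_h", "Dose_mg"],
}


class SchemaError(ValueError):
    """A dataset table does not match the documented schema."""


@dataclass
class TrialDataset:
    covariates: pd.DataFrame
    measurements: pd.DataFrame
    doses: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in _SCHEMAS:
            validate_table(name, getattr(self, name))
        known = set(self.covariates["ID"])
        for name in ("measurements", "doses"):
            ids = set(getattr(self, name)["ID"])
            if not ids <= known:
                raise SchemaError(
                    f"{name} table refers to patient IDs missing from the "
                    f"covariates table: {sorted(ids - known)[:5]}")

    @property
    def n_patients(self) -> int:
        return len(self.covariates)

    def patient_measurements(self, patient_id,
                             observable: str = "INR") -> pd.DataFrame:
        m = self.measurements
        return m[(m["ID"] == patient_id) &
                 (m["Observable"] == observable)].sort_values("Time_h")

    def equals(self, other: "TrialDataset") -> bool:
        return (self.covariates.equals(other.covariates)
                and self.measurements.equals(other.measurements)
                and self.doses.equals(other.doses))


def validate_table(name: str, frame: pd.DataFrame) -> None:
    required = _SCHEMAS[name]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{name} table is missing columns {missing}")
    extra = [c for c in frame.columns if c not in required]
    if extra:
        warnings.warn(f"{name} table carries extra columns {extra}; "
                      "they are preserved but ignored", stacklevel=2)
    if name == "measurements" and len(frame):
        bad = set(frame["Observable"]) - set(OBSERVABLES)
        if bad:
            raise SchemaError(f"unknown observables {sorted(bad)}")
        if (frame["Value"] <= 0).any():
            raise SchemaError("measurement values must be positive")


def write_dataset(dataset: TrialDataset, path) -> None:
    """Write the three CSV tables plus metadata.json into ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for name in _SCHEMAS:
        frame = getattr(dataset, name)
        ordered = _SCHEMAS[name] + [c for c in frame.columns
                                    if c not in _SCHEMAS[name]]
        frame[ordered].to_csv(path / f"{name}.csv", index=False,
                              float_format="%.10g")
    with open(path / "metadata.json", "w") as fh:
        json.dump(dataset.metadata, fh, indent=1, default=str)


def read_dataset(path) -> TrialDataset:
    """Read a dataset directory written by :func:`write_dataset`."""
    path = Path(path)
    float_cols = {"Time_h", "Value", "Dose_mg"}
    tables = {}
    for name in _SCHEMAS:
        csv = path / f"{name}.csv"
        if not csv.exists():
            raise SchemaError(f"missing table file {csv}")
        frame = pd.read_csv(csv)
        for col in float_cols & set(frame.columns):
            frame[col] = frame[col].astype(float)
        tables[name] = frame
    meta_file = path / "metadata.json"
    metadata = json.loads(meta_file.read_text()) if meta_file.exists() else {}
    return TrialDataset(metadata=metadata, **tables)


def maintenance_table(dataset: TrialDataset) -> pd.DataFrame:
    """Per-patient (covariates, maintenance dose, last-day INR) table.

    The maintenance dose is the last recorded dose; the response is the last
    recorded INR measurement.  This is the training table for the regression
    agent.
    """
    inr = dataset.measurements[
        dataset.measurements["Observable"] == "INR"]
    last_inr = (inr.sort_values("Time_h").groupby("ID").tail(1)
                .rename(columns={"Value": "INR"})[["ID", "INR"]])
    last_dose = (dataset.doses.sort_values("Time_h").groupby("ID").tail(1)
                 .rename(columns={"Dose_mg": "MaintenanceDose"})
                 [["ID", "MaintenanceDose"]])
    out = dataset.covariates.merge(last_inr, on="ID").merge(last_dose, on="ID")
    return out.reset_index(drop=True)
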