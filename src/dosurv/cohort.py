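"""Patient-level records: covariates and right-censored outcomes.

Covariates mirror a long-term childhood-cancer survivorship cohort: sex, age
at first-cancer diagnosis in four categories, one-hot indicators for the
first-cancer diagnosis group, and two binary chemotherapy exposures
(anthracyclines, alkylating agents).  The outcome is time in years to a
severe cardiac event, right-censored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AGE_CATEGORIES = ("0-5", "6-10", "11-15", ">15")
#: Dummy-coded age columns; the 0-5 years category is the reference.
AGE_DUMMY_COLUMNS = ("age_6_10", "age_11_15", "age_gt15")


@dataclass
class PatientRecord:
    """One patient's covariates and censored survival outcome."""

    patient_id: str
    sex: int  # 1 = female
    age_category: str  # one of AGE_CATEGORIES
    diagnosis_indicators: np.ndarray  # one-hot over diagnosis groups
    anthracyclines: int
    alkylating_agents: int
    time: float  # years
    event: int  # 1 = severe cardiac event observed
    irradiated: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.age_category not in AGE_CATEGORIES:
            raise ValueError(f"unknown age category {self.age_category!r}")
        self.diagnosis_indicators = np.asarray(self.diagnosis_indicators, dtype=np.int8)
        if self.diagnosis_indicators.sum() != 1:
            raise ValueError("exactly one diagnosis group must be set")
        if self.time <= 0:
            raise ValueError("survival time must be positive")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


def diagnosis_columns(n_groups: int) -> list[str]:
    return [f"diag_{i + 1:02d}" for i in range(n_groups)]


def clinical_frame(records: list[PatientRecord]) -> pd.DataFrame:
    """Clinical + chemotherapy design matrix, indexed by patient id.

    Age is dummy coded against the 0-5 years reference; the diagnosis group
    is expanded into its one-hot indicator columns.
    """
    n_groups = records[0].diagnosis_indicators.size
    rows = []
    for r in records:
        row = {
            "sex": r.sex,
            "age_6_10": int(r.age_category == "6-10"),
            "age_11_15": int(r.age_category == "11-15"),
            "age_gt15": int(r.age_category == ">15"),
            "anthracyclines": r.anthracyclines,
            "alkylating_agents": r.alkylating_agents,
        }
        row.update(dict(zip(diagnosis_columns(n_groups), r.diagnosis_indicators.tolist())))
        rows.append(row)
    return pd.DataFrame(rows, index=pd.Index([r.patient_id for r in records], name="patient_id"))


def outcome_arrays(records: list[PatientRecord]) -> tuple[np.ndarray, np.ndarray]:
    """(time, event) arrays in record order."""
    time = np.array([r.time for r in records], dtype=float)
    event = np.array([r.event for r in records], dtype=int)
    return time, event


def records_frame(records: list[PatientRecord]) -> pd.DataFrame:
    """Full per-patient table (covariates + outcome) for CSV export."""
    df = clinical_frame(records)
    df.insert(0, "age_category", [r.age_category for r in records])
    df["irradiated"] = [int(r.irradiated) for r in records]
    df["time"] = [r.time for r in records]
    df["event"] = [r.event for r in records]
    return df
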