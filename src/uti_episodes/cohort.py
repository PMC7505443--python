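"""Cohort entry/exit intervals and person-years at risk.

A patient enters the cohort at the latest of: the practice's up-to-standard
date, one year of continuous registration, their 65th birthday, and the
study start.  They leave on their date of death or, if alive, 60 days before
the earliest of the practice's last collection date, their transfer-out
date, and the study end — the 60-day buffer guarantees complete outcome
follow-up for every analyzed episode, while patients who die inside the
window remain eligible (dropping them would bias mortality-related
estimates).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import pandas as pd

DAYS_PER_YEAR = 365.25
FOLLOWUP_BUFFER_DAYS = 60
#: "1 year of continuous registration" as plain calendar-day arithmetic.
REGISTRATION_RUN_IN_DAYS = 365

_MANDATORY = (
    "birth_date",
    "registration_start",
    "registration_end",
    "up_to_standard_date",
    "last_collection_date",
)


@dataclass(frozen=True)
class CohortInterval:
    patient_id: int
    entry_date: pd.Timestamp | None
    exit_date: pd.Timestamp | None
    eligible: bool
    person_years: float


def compute_cohort_interval(
    patient, study_start: date | pd.Timestamp, study_end: date | pd.Timestamp
) -> CohortInterval:
    """At-risk interval for one registry row (mapping or pandas Series)."""
    for f in _MANDATORY:
        v = patient.get(f) if hasattr(patient, "get") else patient[f]
        if v is None or pd.isna(v):
            raise ValueError(f"missing mandatory registry date: {f}")

    study_start = pd.Timestamp(study_start)
    study_end = pd.Timestamp(study_end)
    birth = pd.Timestamp(patient["birth_date"])
    sixty_fifth = birth + pd.DateOffset(years=65)
    entry = max(
        pd.Timestamp(patient["up_to_standard_date"]),
        pd.Timestamp(patient["registration_start"]) + pd.Timedelta(days=REGISTRATION_RUN_IN_DAYS),
        sixty_fifth,
        study_start,
    )
    death = patient.get("death_date")
    censor = min(
        pd.Timestamp(patient["last_collection_date"]),
        pd.Timestamp(patient["registration_end"]),
        study_end,
    ) - pd.Timedelta(days=FOLLOWUP_BUFFER_DAYS)
    if death is not None and pd.notna(death):
        exit_date = pd.Timestamp(death)
    else:
        exit_date = censor
    eligible = bool(entry <= exit_date)
    py = (exit_date - entry).days / DAYS_PER_YEAR if eligible else 0.0
    return CohortInterval(
        patient_id=int(patient["patient_id"]),
        entry_date=entry if eligible else None,
        exit_date=exit_date if eligible else None,
        eligible=eligible,
        person_years=py,
    )


def compute_cohort(
    patients: pd.DataFrame, study_start: date | pd.Timestamp, study_end: date | pd.Timestamp
) -> pd.DataFrame:
    """Vectorised :func:`compute_cohort_interval` over a registry table.

    Returns columns ``patient_id, entry, exit, eligible, person_years``.
    """
    for f in _MANDATORY:
        if patients[f].isna().any():
            bad = patients.loc[patients[f].isna(), "patient_id"].iloc[0]
            raise ValueError(f"missing mandatory registry date: {f} (patient {bad})")
    study_start = pd.Timestamp(study_start)
    study_end = pd.Timestamp(study_end)

    birth = pd.DatetimeIndex(patients["birth_date"])
    sixty_fifth = pd.Series(birth + pd.DateOffset(years=65), index=patients.index)
    entry = pd.concat(
        [
            patients["up_to_standard_date"],
            patients["registration_start"] + pd.Timedelta(days=REGISTRATION_RUN_IN_DAYS),
            sixty_fifth,
            pd.Series(study_start, index=patients.index),
        ],
        axis=1,
    ).max(axis=1)
    censor = pd.concat(
        [
            patients["last_collection_date"],
            patients["registration_end"],
            pd.Series(study_end, index=patients.index),
        ],
        axis=1,
    ).min(axis=1) - pd.Timedelta(days=FOLLOWUP_BUFFER_DAYS)
    exit_date = patients["death_date"].fillna(censor)
    eligible = entry <= exit_date
    py = ((exit_date - entry).dt.days / DAYS_PER_YEAR).where(eligible, 0.0)
    return pd.DataFrame(
        {
            "patient_id": patients["patient_id"].to_numpy(),
            "entry": entry.where(eligible, pd.NaT).to_numpy(),
            "exit": exit_date.where(eligible, pd.NaT).to_numpy(),
            "eligible": eligible.to_numpy(),
            "person_years": py.to_numpy(),
        }
    )
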