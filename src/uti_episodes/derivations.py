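"""Flattening analyzed episodes into analysis rows.

Each analyzed episode becomes one row carrying the exposure (immediate
versus not-immediate antibiotic prescribing), 60-day outcomes (coded-sepsis
BSI, all-cause death, hospitalisation unrelated to UTI/BSI), the BSI source
classification, and every baseline covariate used by the models: age,
gender, deprivation quintile, region, NHS financial year, weighted Charlson
comorbidity index, smoking status, recurrent-UTI history, prior
hospital/A&E/antibiotic utilisation, and whether the index consultation was
a home visit.

Covariates are derived from history strictly before the episode start; the
"prior year/30/7 days" windows end the day before the start so the index-day
prescription (which defines the exposure) never leaks into a covariate.
Outcome windows include day 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from uti_episodes.codelist import charlson_weights
from uti_episodes.cohort import compute_cohort
from uti_episodes.episodes import build_episodes, DEFAULT_WINDOW_DAYS
from uti_episodes.synthetic_ehr import REGIONS

#: model candidate covariates, in Table-1 order
CANDIDATE_COVARIATES = [
    "age_per5", "female", "imd_quintile", "region", "financial_year",
    "cci_sqrt", "smoking", "recurrent_uti", "discharged_7d", "discharged_30d",
    "hosp_days_prior_year_sqrt", "admissions_prior_year_sqrt",
    "ae_30d", "ae_attendances_prior_year_sqrt", "abx_30d", "home_visit",
]
CATEGORICAL_COVARIATES = {"imd_quintile", "region", "financial_year", "smoking"}

_SQRT_FIELDS = {
    "cci_raw": "cci_sqrt",
    "admissions_prior_year": "admissions_prior_year_sqrt",
    "hosp_days_prior_year": "hosp_days_prior_year_sqrt",
    "ae_attendances_prior_year": "ae_attendances_prior_year_sqrt",
}

_PROPHYLAXIS_SUBSTANCES = ("nitrofurantoin", "trimethoprim")
_PROPHYLAXIS_MIN_DAYS = 28


# ---------------------------------------------------------------------------
# Single-episode operations (day-offset integer arithmetic)


def classify_exposure(start: int, issue_days) -> tuple[str, bool]:
    """Exposure group from systemic-antibiotic issue dates.

    Immediate iff any prescription on the start day; otherwise
    not-immediate, with a delayed-prescription subflag for any issue on days
    1-7 after (but not including) the start.  Delayed and never-treated form
    a single comparison group.
    """
    issue_days = np.asarray(issue_days)
    if issue_days.size and np.any(issue_days == start):
        return "immediate", False
    delayed = bool(issue_days.size and np.any((issue_days >= start + 1) & (issue_days <= start + 7)))
    return "not_immediate", delayed


def ascertain_bsi(start: int, window_days: int, sepsis_days) -> tuple[bool, float]:
    """(bsi flag, days to earliest coded sepsis) within [start, start+window]."""
    sepsis_days = np.asarray(sepsis_days)
    if sepsis_days.size == 0:
        return False, math.nan
    in_win = sepsis_days[(sepsis_days >= start) & (sepsis_days <= start + window_days)]
    if in_win.size == 0:
        return False, math.nan
    return True, float(in_win.min() - start)


def classify_bsi_source(hospital_sepsis: list[tuple[str, int]],
                        window_spells: list[dict],
                        bsi_60: bool = True) -> dict:
    """Source category of a BSI episode.

    ``hospital_sepsis`` holds (subcategory, diagnosis position) for sepsis
    diagnoses of spells admitted in the outcome window; ``window_spells``
    holds per-spell flags (``has_uti``, ``has_other_infection``) for the
    same spells.  Hospital-confirmed cases follow the hierarchy
    urosepsis > other-infectious > unspecified; primary-care-only cases are
    subclassified by what the hospital record in the window shows.
    """
    if not bsi_60:
        raise ValueError("classify_bsi_source requires an episode with bsi_60=True")
    out = {"setting": "", "category": "", "primary_reason": False, "lower_respiratory": False}
    if hospital_sepsis:
        subs = [s for s, _ in hospital_sepsis]
        if any(s == "urosepsis" for s in subs):
            cat = "urosepsis"
        elif any(s.startswith("other_infectious") for s in subs):
            cat = "other_infectious"
        else:
            cat = "unspecified"
        chosen = [
            (s, p) for s, p in hospital_sepsis
            if (s == cat) or (cat == "other_infectious" and s.startswith("other_infectious"))
        ]
        out["setting"] = "hospital"
        out["category"] = cat
        out["primary_reason"] = any(p == 1 for _, p in chosen)
        if cat == "other_infectious":
            out["lower_respiratory"] = any(s == "other_infectious:lower_respiratory" for s, _ in chosen)
        return out
    out["setting"] = "primary_care_only"
    if not window_spells:
        out["category"] = "no_hospitalization"
    elif any(sp["has_uti"] for sp in window_spells):
        out["category"] = "uti_code_in_hospital"
    elif any(sp["has_other_infection"] for sp in window_spells):
        out["category"] = "other_infection_in_hospital"
    else:
        out["category"] = "no_infection_in_hospital"
    return out


def ascertain_secondary_outcomes(start: int, window_days: int, death_day,
                                 spells: list[dict]) -> tuple[bool, bool]:
    """(death within window, admission unrelated to UTI/BSI within window)."""
    death_60 = death_day is not None and start <= death_day <= start + window_days
    other = any(
        start <= sp["adm"] <= start + window_days
        and not sp["has_uti"] and not sp["has_sepsis"]
        for sp in spells
    )
    return bool(death_60), bool(other)


def transform_counts(rows: pd.DataFrame) -> pd.DataFrame:
    """Add square-root copies of the count covariates (in place, returned)."""
    for raw, tr in _SQRT_FIELDS.items():
        rows[tr] = np.sqrt(rows[raw].astype(float))
    return rows


# ---------------------------------------------------------------------------
# Per-patient history container


@dataclass
class PatientHistory:
    female: bool = False
    birth: int = 0
    imd: object = None
    region: str = ""
    death_day: int | None = None
    abx_days: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    prophylaxis_days: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    uti_pc_days: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    home_visit_days: set = field(default_factory=set)
    sepsis_days: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    ae_days: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    smoking: list = field(default_factory=list)        # (day, sub)
    comorbid: list = field(default_factory=list)       # (day, group)
    recurrent_code_days: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    spells: list = field(default_factory=list)         # dicts: adm, dis, has_uti, has_sepsis, has_other_infection, sepsis: [(sub, pos)]


def derive_covariates(h: PatientHistory, start: int, weights: dict[str, int]) -> dict:
    """All baseline covariates for an episode starting on day ``start``."""
    b365, e = start - 365, start - 1
    age = int((start - h.birth) // 365.25)
    cci = sum(
        w for g, w in (
            (g, weights[g]) for g in {g for d, g in h.comorbid if d < start}
        )
    )
    prior = [(d, s) for d, s in h.smoking if d < start]
    if not prior:
        smoking = "non"
    else:
        prior.sort()
        latest = prior[-1][1]
        if latest == "non":
            smoking = "ex" if any(s in ("current", "ex") for _, s in prior[:-1]) else "non"
        else:
            smoking = latest
    n_uti_prior = int(np.sum((h.uti_pc_days >= b365) & (h.uti_pc_days <= e)))
    recurrent = bool(
        np.any(h.recurrent_code_days < start)
        or np.any(h.prophylaxis_days < start)
        or n_uti_prior >= 2
    )
    adm = np.array([sp["adm"] for sp in h.spells], dtype=np.int64)
    dis = np.array([sp["dis"] for sp in h.spells], dtype=np.int64)
    in_year = (adm >= b365) & (adm <= e)
    hosp_days = int(np.sum(np.maximum(0, np.minimum(dis, e) - np.maximum(adm, b365)))) if adm.size else 0
    return {
        "age_years": age,
        "age_per5": age / 5.0,
        "female": int(h.female),
        "imd_quintile": h.imd,
        "region": h.region,
        "cci_raw": int(cci),
        "smoking": smoking,
        "recurrent_uti": int(recurrent),
        "discharged_7d": int(bool(adm.size and np.any((dis >= start - 7) & (dis <= e)))),
        "discharged_30d": int(bool(adm.size and np.any((dis >= start - 30) & (dis <= e)))),
        "hosp_days_prior_year": hosp_days,
        "admissions_prior_year": int(in_year.sum()) if adm.size else 0,
        "ae_attendances_prior_year": int(np.sum((h.ae_days >= b365) & (h.ae_days <= e))),
        "ae_30d": int(bool(np.any((h.ae_days >= start - 30) & (h.ae_days <= e)))),
        "abx_30d": int(bool(np.any((h.abx_days >= start - 30) & (h.abx_days <= e)))),
        "home_visit": int(start in h.home_visit_days),
    }


def _financial_year(day: int) -> str:
    ts = pd.Timestamp(day, unit="D")
    y = ts.year if ts.month >= 4 else ts.year - 1
    return f"{y}/{(y + 1) % 100:02d}"


def _day_ints(s: pd.Series) -> np.ndarray:
    return s.to_numpy(dtype="datetime64[D]").astype(np.int64)


def _build_histories(bundle) -> dict[int, PatientHistory]:
    weights = charlson_weights()
    hist: dict[int, PatientHistory] = {}

    for row in bundle.patients.itertuples(index=False):
        h = PatientHistory(
            female=row.gender == "female",
            birth=int(pd.Timestamp(row.birth_date).value // 86_400_000_000_000),
            imd=(None if pd.isna(row.imd_quintile) else f"Q{int(row.imd_quintile)}"),
            region=row.region or None,
            death_day=None if pd.isna(row.death_date) else int(pd.Timestamp(row.death_date).value // 86_400_000_000_000),
        )
        hist[row.patient_id] = h

    rx = bundle.prescriptions
    rx_abx = rx[rx["is_systemic_antibiotic"] == 1]
    days = _day_ints(rx_abx["issue_date"])
    proph = (
        rx_abx["substance"].isin(_PROPHYLAXIS_SUBSTANCES)
        & (rx_abx["duration_days"].fillna(0).astype(int) >= _PROPHYLAXIS_MIN_DAYS)
    ).to_numpy()
    for pid, idx in rx_abx.groupby("patient_id").indices.items():
        hist[pid].abx_days = days[idx]
        hist[pid].prophylaxis_days = days[idx][proph[idx]]

    ev = bundle.events
    ev_days = _day_ints(ev["event_date"])
    cats = ev["category"].to_numpy()
    subs = ev["subcategory"].to_numpy()
    hv = ev["home_visit"].to_numpy()
    for pid, idx in ev.groupby("patient_id").indices.items():
        h = hist[pid]
        c = cats[idx]
        d = ev_days[idx]
        h.uti_pc_days = d[c == "uti"]
        h.home_visit_days = set(d[(c == "uti") & (hv[idx] == 1)].tolist())
        pc_sepsis = d[c == "sepsis"]
        h.sepsis_days = pc_sepsis
        h.smoking = list(zip(d[c == "smoking_status"].tolist(), subs[idx][c == "smoking_status"].tolist()))
        como = np.char.startswith(c.astype(str), "comorbidity:")
        h.comorbid = [
            (dd, cc.split(":", 1)[1]) for dd, cc in zip(d[como].tolist(), c[como].tolist())
        ]
        h.recurrent_code_days = d[c == "recurrent_uti"]

    sp = bundle.spells
    if len(sp):
        adm_days = _day_ints(sp["admission_date"])
        dis_days = _day_ints(sp["discharge_date"])
        sp_cats = sp["category"].to_numpy()
        sp_subs = sp["subcategory"].to_numpy()
        sp_pos = sp["position"].to_numpy()
        for (pid, _sid), idx in sp.groupby(["patient_id", "spell_id"]).indices.items():
            c = sp_cats[idx]
            entry = {
                "adm": int(adm_days[idx[0]]),
                "dis": int(dis_days[idx[0]]),
                "has_uti": bool(np.any(c == "uti")),
                "has_sepsis": bool(np.any(c == "sepsis")),
                "has_other_infection": bool(np.any(c == "other_infection")),
                "sepsis": [
                    (sp_subs[i], int(sp_pos[i])) for i in idx if sp_cats[i] == "sepsis"
                ],
            }
            hist[pid].spells.append(entry)

    ae_days_all = _day_ints(bundle.ae["attendance_date"])
    for pid, idx in bundle.ae.groupby("patient_id").indices.items():
        hist[pid].ae_days = ae_days_all[idx]
    for h in hist.values():
        h.spells.sort(key=lambda s: s["adm"])
    return hist


def build_analysis_rows(
    bundle,
    study_start,
    study_end,
    window_days: int = DEFAULT_WINDOW_DAYS,
    cohort: pd.DataFrame | None = None,
    episodes_df: pd.DataFrame | None = None,
    drop_missing_demographics: bool = True,
) -> pd.DataFrame:
    """Run cohort -> episodes -> derivations and return the analysis table.

    One row per analyzed episode; flags are 0/1; categorical covariates are
    pandas Categoricals with the model reference level first (IMD Q1, South
    of England, earliest financial year, nonsmoker).  The result carries
    ``attrs``: episode/exclusion counts and the number of rows dropped for
    missing IMD or region.
    """
    if cohort is None:
        cohort = compute_cohort(bundle.patients, study_start, study_end)
    if episodes_df is None:
        episodes_df = build_episodes(bundle, cohort, window_days=window_days)
    hist = _build_histories(bundle)
    weights = charlson_weights()

    analyzed = episodes_df[episodes_df["status"] == "analyzed"]
    recs = []
    for row in analyzed.itertuples(index=False):
        pid = row.patient_id
        h = hist[pid]
        start = int(pd.Timestamp(row.start).value // 86_400_000_000_000)

        exposure, delayed = classify_exposure(start, h.abx_days)
        cov = derive_covariates(h, start, weights)

        sp_sepsis_days = np.array(
            [sp["adm"] for sp in h.spells if sp["has_sepsis"]], dtype=np.int64
        )
        all_sepsis = np.concatenate([h.sepsis_days, sp_sepsis_days])
        bsi_60, days_to = ascertain_bsi(start, window_days, all_sepsis)

        window_spells = [
            sp for sp in h.spells if start <= sp["adm"] <= start + window_days
        ]
        if bsi_60:
            hosp_sepsis = [
                (s, p) for sp in window_spells for s, p in sp["sepsis"]
            ]
            src = classify_bsi_source(hosp_sepsis, window_spells, True)
        else:
            src = {"setting": "", "category": "", "primary_reason": False,
                   "lower_respiratory": False}

        death_60, other_hosp_60 = ascertain_secondary_outcomes(
            start, window_days, h.death_day, h.spells
        )

        recs.append({
            "patient_id": pid,
            "episode_index": int(row.episode_index),
            "start_date": row.start,
            "exposure": exposure,
            "not_immediate": int(exposure == "not_immediate"),
            "delayed_rx": int(delayed),
            "financial_year": _financial_year(start),
            **cov,
            "bsi_60": int(bsi_60),
            "days_to_bsi": days_to,
            "death_60": int(death_60),
            "other_hosp_60": int(other_hosp_60),
            "bsi_setting": src["setting"],
            "bsi_source": src["category"],
            "bsi_primary_reason": int(src["primary_reason"]),
            "bsi_lower_respiratory": int(src["lower_respiratory"]),
        })

    rows = pd.DataFrame(recs)
    n_missing = 0
    if len(rows):
        missing = rows["imd_quintile"].isna() | rows["region"].isna()
        n_missing = int(missing.sum())
        if drop_missing_demographics:
            rows = rows.loc[~missing].reset_index(drop=True)
        rows["imd_quintile"] = pd.Categorical(
            rows["imd_quintile"], categories=[f"Q{i}" for i in range(1, 6)]
        )
        rows["region"] = pd.Categorical(rows["region"], categories=list(REGIONS))
        fy = sorted(rows["financial_year"].unique())
        rows["financial_year"] = pd.Categorical(rows["financial_year"], categories=fy)
        rows["smoking"] = pd.Categorical(
            rows["smoking"], categories=["non", "ex", "current"]
        )
        rows = transform_counts(rows)

    rows.attrs["n_analyzed_episodes"] = int(len(analyzed))
    rows.attrs["n_missing_demographics"] = n_missing
    rows.attrs["status_counts"] = episodes_df["status"].value_counts().to_dict()
    rows.attrs["window_days"] = window_days
    return rows
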