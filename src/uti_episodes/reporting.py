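"""Descriptive tables, worked-example utilities and the attrition flow.

Mirrors the shape of the study's published tables: baseline characteristics
by exposure group (medians/IQRs with Wilcoxon rank-sum tests for continuous
variables, counts/percentages with chi-square tests for categorical ones),
the BSI source hierarchy by healthcare setting, and simple closed-form
utilities (2x2 odds ratio with Wald CI, episode rate per 1,000
patient-years) used for arithmetic checks against printed counts.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from uti_episodes.estimation import Z95

CONTINUOUS_VARS = [
    "age_years", "cci_raw", "hosp_days_prior_year", "admissions_prior_year",
    "ae_attendances_prior_year",
]
CATEGORICAL_VARS = [
    "female", "imd_quintile", "region", "financial_year", "smoking",
    "recurrent_uti", "discharged_7d", "discharged_30d", "ae_30d", "abx_30d",
    "home_visit", "bsi_60", "other_hosp_60", "death_60",
]


def _median_iqr(v: pd.Series) -> str:
    q1, med, q3 = np.percentile(v.dropna().astype(float), [25, 50, 75])
    return f"{med:g} [{q1:g}-{q3:g}]"


def descriptive_table(rows: pd.DataFrame) -> pd.DataFrame:
    """Table-1-shaped summary comparing exposure groups.

    One output row per variable level: counts and group-denominator
    percentages (categorical) or median [IQR] (continuous), with the
    between-group p-value attached to the variable's first row.  Degenerate
    (constant) continuous variables are flagged instead of tested.
    """
    imm = rows[rows["exposure"] == "immediate"]
    nim = rows[rows["exposure"] == "not_immediate"]
    out = []

    out.append({
        "variable": "total", "level": "", "test": "",
        "n_overall": len(rows), "pct_overall": 100.0,
        "n_immediate": len(imm), "pct_immediate": 100 * len(imm) / max(1, len(rows)),
        "n_not_immediate": len(nim), "pct_not_immediate": 100 * len(nim) / max(1, len(rows)),
        "p_value": math.nan, "flag": "",
    })

    for var in CONTINUOUS_VARS:
        if var not in rows.columns:
            continue
        degenerate = rows[var].nunique(dropna=True) < 2
        if degenerate or len(imm) == 0 or len(nim) == 0:
            p, flag = math.nan, "degenerate"
        else:
            p = float(stats.mannwhitneyu(imm[var], nim[var], alternative="two-sided").pvalue)
            flag = ""
        out.append({
            "variable": var, "level": "median_iqr", "test": "wilcoxon_rank_sum",
            "stat_overall": _median_iqr(rows[var]),
            "stat_immediate": _median_iqr(imm[var]) if len(imm) else "",
            "stat_not_immediate": _median_iqr(nim[var]) if len(nim) else "",
            "p_value": p, "flag": flag,
        })

    for var in CATEGORICAL_VARS:
        if var not in rows.columns:
            continue
        tab = pd.crosstab(rows[var], rows["exposure"])
        for g in ("immediate", "not_immediate"):
            if g not in tab.columns:
                tab[g] = 0
        if tab.shape[0] >= 2 and (tab.to_numpy().sum(axis=0) > 0).all():
            p = float(stats.chi2_contingency(tab.to_numpy(), correction=False).pvalue)
            flag = ""
        else:
            p, flag = math.nan, "degenerate"
        first = True
        for level, r in tab.iterrows():
            n_all = int(r.sum())
            out.append({
                "variable": var, "level": str(level), "test": "chi2",
                "n_overall": n_all,
                "pct_overall": 100 * n_all / max(1, len(rows)),
                "n_immediate": int(r["immediate"]),
                "pct_immediate": 100 * r["immediate"] / max(1, len(imm)),
                "n_not_immediate": int(r["not_immediate"]),
                "pct_not_immediate": 100 * r["not_immediate"] / max(1, len(nim)),
                "p_value": p if first else math.nan, "flag": flag,
            })
            first = False
    return pd.DataFrame(out)


def crude_or_2x2(
    cases_exposed: int, noncases_exposed: int,
    cases_unexposed: int, noncases_unexposed: int,
) -> dict:
    """Odds ratio (a*d)/(b*c) with log-scale Wald 95% CI from 2x2 counts."""
    a, b, c, d = cases_exposed, noncases_exposed, cases_unexposed, noncases_unexposed
    for nm, v in (("cases_exposed", a), ("noncases_exposed", b),
                  ("cases_unexposed", c), ("noncases_unexposed", d)):
        if v < 0:
            raise ValueError(f"{nm} must be >= 0")
        if v == 0:
            raise ValueError(
                f"zero cell ({nm}); continuity corrections are out of scope"
            )
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return {
        "or": math.exp(log_or),
        "ci_low": math.exp(log_or - Z95 * se),
        "ci_high": math.exp(log_or + Z95 * se),
        "log_or": log_or,
        "se": se,
    }


def rate_per_1000py(n_events: float, person_years: float) -> float:
    """Events per 1,000 person-years."""
    if person_years <= 0:
        raise ValueError("person_years must be positive")
    return 1000.0 * n_events / person_years


_T3_ROWS = [
    ("total", None, None),
    ("hospital_confirmed", "hospital", None),
    ("urosepsis", "hospital", "urosepsis"),
    ("urosepsis_primary_reason", "hospital", "urosepsis_primary"),
    ("other_infectious", "hospital", "other_infectious"),
    ("other_infectious_lower_respiratory", "hospital", "lower_respiratory"),
    ("unspecified", "hospital", "unspecified"),
    ("primary_care_only", "primary_care_only", None),
    ("uti_code_in_hospital", "primary_care_only", "uti_code_in_hospital"),
    ("other_infection_in_hospital", "primary_care_only", "other_infection_in_hospital"),
    ("no_infection_in_hospital", "primary_care_only", "no_infection_in_hospital"),
    ("no_hospitalization", "primary_care_only", "no_hospitalization"),
]


def bsi_source_table(rows: pd.DataFrame) -> pd.DataFrame:
    """Source-of-BSI hierarchy by exposure group.

    Hospital-confirmed and primary-care-only counts partition the total per
    group; "of which" sub-rows nest within their parent.  Percentages are
    given of the group total and of the setting subtotal.
    """
    bsi = rows[rows["bsi_60"] == 1]
    out = []
    for label, setting, sub in _T3_ROWS:
        rec = {"row": label}
        for g, gname in (("immediate", "immediate"), ("not_immediate", "not_immediate")):
            grp = bsi[bsi["exposure"] == g]
            total = len(grp)
            in_setting = grp if setting is None else grp[grp["bsi_setting"] == setting]
            if sub is None:
                n = len(in_setting)
            elif sub == "urosepsis_primary":
                n = int(((in_setting["bsi_source"] == "urosepsis")
                         & (in_setting["bsi_primary_reason"] == 1)).sum())
            elif sub == "lower_respiratory":
                n = int(((in_setting["bsi_source"] == "other_infectious")
                         & (in_setting["bsi_lower_respiratory"] == 1)).sum())
            else:
                n = int((in_setting["bsi_source"] == sub).sum())
            setting_total = len(in_setting) if sub is not None else total
            rec[f"{gname}_n"] = n
            rec[f"{gname}_pct_total"] = 100 * n / total if total else math.nan
            rec[f"{gname}_pct_setting"] = (
                100 * n / setting_total if setting_total else math.nan
            )
        out.append(rec)
    return pd.DataFrame(out)


def attrition_flow(patients, cohort, episodes_df, rows) -> dict:
    """Counts at each attrition step of the pipeline."""
    status_counts = episodes_df["status"].value_counts().to_dict()
    return {
        "n_patients_registry": int(len(patients)),
        "n_patients_eligible": int(cohort["eligible"].sum()),
        "person_years": float(cohort["person_years"].sum()),
        "n_episode_records": int(len(episodes_df)),
        "episode_status_counts": {k: int(v) for k, v in status_counts.items()},
        "n_analyzed_episodes": int(status_counts.get("analyzed", 0)),
        "n_rows_missing_demographics": int(rows.attrs.get("n_missing_demographics", 0)),
        "n_analysis_rows": int(len(rows)),
        "n_immediate": int((rows["exposure"] == "immediate").sum()) if len(rows) else 0,
        "n_not_immediate": int((rows["exposure"] == "not_immediate").sum()) if len(rows) else 0,
        "n_patients_analyzed": int(rows["patient_id"].nunique()) if len(rows) else 0,
    }
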