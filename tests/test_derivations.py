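"""Exposure, outcome, source-of-BSI and covariate derivations."""

import math

import numpy as np
import pandas as pd
import pytest

from uti_episodes.codelist import charlson_weights
from uti_episodes.derivations import (
    PatientHistory,
    ascertain_bsi,
    ascertain_secondary_outcomes,
    classify_bsi_source,
    classify_exposure,
    derive_covariates,
    transform_counts,
    build_analysis_rows,
)


# --- exposure --------------------------------------------------------------

@pytest.mark.parametrize(
    "issues,expected",
    [
        ([0], ("immediate", False)),
        ([3], ("not_immediate", True)),
        ([7], ("not_immediate", True)),
        ([8], ("not_immediate", False)),
        ([], ("not_immediate", False)),
        ([0, 3], ("immediate", False)),
        ([-5], ("not_immediate", False)),
    ],
)
def test_classify_exposure_windows(issues, expected):
    assert classify_exposure(0, np.array(issues, dtype=int)) == expected


# --- BSI ascertainment -----------------------------------------------------

def test_bsi_found_within_window_with_days_to_event():
    assert ascertain_bsi(100, 60, np.array([120])) == (True, 20.0)


def test_bsi_boundaries():
    assert ascertain_bsi(0, 60, np.array([60]))[0] is True
    assert ascertain_bsi(0, 60, np.array([61]))[0] is False
    assert ascertain_bsi(0, 60, np.array([]))[0] is False


def test_bsi_earliest_evidence_wins():
    flag, days = ascertain_bsi(0, 60, np.array([45, 10, 30]))
    assert flag and days == 10.0


# --- BSI source classification --------------------------------------------

def test_primary_position_urosepsis_is_hospital_confirmed_primary_reason():
    out = classify_bsi_source([("urosepsis", 1)], [{"has_uti": False, "has_other_infection": False}])
    assert out["setting"] == "hospital"
    assert out["category"] == "urosepsis"
    assert out["primary_reason"] is True


def test_hierarchy_prefers_urosepsis_over_unspecified():
    out = classify_bsi_source([("unspecified", 1), ("urosepsis", 2)], [])
    assert out["category"] == "urosepsis"
    assert out["primary_reason"] is False  # the urosepsis code is not position 1


def test_other_infectious_with_lower_respiratory_subflag():
    out = classify_bsi_source([("other_infectious:lower_respiratory", 2)], [])
    assert out["category"] == "other_infectious"
    assert out["lower_respiratory"] is True


def test_primary_care_only_subclassification():
    no_hosp = classify_bsi_source([], [])
    assert (no_hosp["setting"], no_hosp["category"]) == ("primary_care_only", "no_hospitalization")
    uti = classify_bsi_source([], [{"has_uti": True, "has_other_infection": False}])
    assert uti["category"] == "uti_code_in_hospital"
    inf = classify_bsi_source([], [{"has_uti": False, "has_other_infection": True}])
    assert inf["category"] == "other_infection_in_hospital"
    none = classify_bsi_source([], [{"has_uti": False, "has_other_infection": False}])
    assert none["category"] == "no_infection_in_hospital"


def test_source_classification_requires_bsi():
    with pytest.raises(ValueError, match="bsi"):
        classify_bsi_source([], [], bsi_60=False)


# --- secondary outcomes ----------------------------------------------------

def test_death_on_day_sixty_counts():
    assert ascertain_secondary_outcomes(0, 60, 60, [])[0] is True
    assert ascertain_secondary_outcomes(0, 60, 61, [])[0] is False


def test_other_hospitalization_excludes_uti_and_sepsis_admissions():
    com = {"adm": 10, "dis": 12, "has_uti": False, "has_sepsis": False, "has_other_infection": False}
    uti = {"adm": 10, "dis": 12, "has_uti": True, "has_sepsis": False, "has_other_infection": False}
    sep = {"adm": 10, "dis": 12, "has_uti": False, "has_sepsis": True, "has_other_infection": False}
    assert ascertain_secondary_outcomes(0, 60, None, [com])[1] is True
    assert ascertain_secondary_outcomes(0, 60, None, [uti])[1] is False
    assert ascertain_secondary_outcomes(0, 60, None, [sep])[1] is False
    late = dict(com, adm=61)
    assert ascertain_secondary_outcomes(0, 60, None, [late])[1] is False


# --- covariates ------------------------------------------------------------

W = charlson_weights()


def _history(**kw):
    h = PatientHistory(female=True, birth=-365 * 70, imd="Q2", region="London")
    for k, v in kw.items():
        setattr(h, k, v)
    return h


def test_recurrent_uti_from_two_consultations_within_a_year():
    h = _history(uti_pc_days=np.array([-100, -200]))
    assert derive_covariates(h, 0, W)["recurrent_uti"] == 1
    h = _history(uti_pc_days=np.array([-100, -400]))
    assert derive_covariates(h, 0, W)["recurrent_uti"] == 0


def test_recurrent_uti_from_prophylactic_prescription():
    h = _history(prophylaxis_days=np.array([-300]))
    assert derive_covariates(h, 0, W)["recurrent_uti"] == 1


def test_recurrent_uti_from_explicit_code():
    h = _history(recurrent_code_days=np.array([-700]))
    assert derive_covariates(h, 0, W)["recurrent_uti"] == 1


def test_smoking_latest_nonsmoker_with_prior_smoking_is_ex():
    h = _history(smoking=[(-500, "current"), (-100, "non")])
    assert derive_covariates(h, 0, W)["smoking"] == "ex"


def test_smoking_defaults_to_nonsmoker_without_codes():
    assert derive_covariates(_history(), 0, W)["smoking"] == "non"


def test_smoking_latest_code_wins_otherwise():
    h = _history(smoking=[(-500, "non"), (-100, "current")])
    assert derive_covariates(h, 0, W)["smoking"] == "current"


def test_cci_sums_weights_over_distinct_groups_before_start():
    h = _history(comorbid=[(-100, "renal_disease"), (-50, "renal_disease"),
                           (-30, "dementia"), (5, "metastatic_tumour")])
    cov = derive_covariates(h, 0, W)
    assert cov["cci_raw"] == W["renal_disease"] + W["dementia"]  # 2 + 1


def test_utilization_windows_end_the_day_before_start():
    h = _history(
        abx_days=np.array([0, -30, -31]),
        ae_days=np.array([-30, -31, -400]),
        spells=[{"adm": -20, "dis": -10, "has_uti": False, "has_sepsis": False,
                 "has_other_infection": False, "sepsis": []}],
    )
    cov = derive_covariates(h, 0, W)
    assert cov["abx_30d"] == 1          # day -30 inside; day 0 excluded
    assert cov["ae_30d"] == 1
    assert cov["ae_attendances_prior_year"] == 2
    assert cov["admissions_prior_year"] == 1
    assert cov["hosp_days_prior_year"] == 10
    assert cov["discharged_7d"] == 0
    assert cov["discharged_30d"] == 1


def test_age_in_completed_years_and_per5():
    h = _history(birth=0)
    cov = derive_covariates(h, int(70.9 * 365.25), W)
    assert cov["age_years"] == 70
    assert cov["age_per5"] == 14.0


@pytest.mark.parametrize("count,root", [(0, 0.0), (4, 2.0), (2, math.sqrt(2))])
def test_sqrt_transforms(count, root):
    rows = pd.DataFrame({
        "cci_raw": [count], "admissions_prior_year": [count],
        "hosp_days_prior_year": [count], "ae_attendances_prior_year": [count],
    })
    out = transform_counts(rows)
    assert out["cci_sqrt"][0] == pytest.approx(root, abs=1e-9)
    assert out["admissions_prior_year_sqrt"][0] == pytest.approx(root, abs=1e-9)


# --- whole-table invariants ------------------------------------------------

def test_exposure_groups_partition_analyzed_episodes(null_rows):
    n_imm = (null_rows["exposure"] == "immediate").sum()
    n_nim = (null_rows["exposure"] == "not_immediate").sum()
    assert n_imm + n_nim == len(null_rows)


def test_bsi_source_categories_partition_bsi_rows(null_rows):
    bsi = null_rows[null_rows["bsi_60"] == 1]
    assert (bsi["bsi_setting"].isin(["hospital", "primary_care_only"])).all()
    assert (null_rows.loc[null_rows["bsi_60"] == 0, "bsi_source"] == "").all()
    assert bsi["days_to_bsi"].between(0, 60).all()


def test_covariates_ignore_post_start_history(null_bundle):
    # mutation test: appending events/prescriptions after each episode start
    # must leave every covariate untouched
    sc, b = null_bundle
    rows = build_analysis_rows(b, sc.study_start, sc.study_end)
    mutated_events = b.events.copy()
    extra = (
        rows.sort_values(["patient_id", "start_date"])
        .groupby("patient_id", observed=True).tail(1)
        .head(40)[["patient_id", "start_date"]].copy()
    )
    add_ev = pd.DataFrame({
        "patient_id": extra["patient_id"],
        "event_date": extra["start_date"] + pd.Timedelta(days=8),
        "setting": "primary_care", "code": "PC-CCI-METS-01",
        "category": "comorbidity:metastatic_tumour", "subcategory": "",
        "home_visit": 0,
    })
    mutated_events = pd.concat([mutated_events, add_ev], ignore_index=True)
    add_rx = pd.DataFrame({
        "patient_id": extra["patient_id"],
        "issue_date": extra["start_date"] + pd.Timedelta(days=9),
        "is_systemic_antibiotic": 1, "substance": "nitrofurantoin",
        "duration_days": 30,
    })
    from dataclasses import replace as dreplace

    b2 = dreplace(
        b,
        events=mutated_events.sort_values(["patient_id", "event_date"], kind="stable").reset_index(drop=True),
        prescriptions=pd.concat([b.prescriptions, add_rx], ignore_index=True)
        .sort_values(["patient_id", "issue_date"], kind="stable").reset_index(drop=True),
    )
    rows2 = build_analysis_rows(b2, sc.study_start, sc.study_end)
    cov_cols = ["age_years", "female", "imd_quintile", "region", "cci_raw", "smoking",
                "recurrent_uti", "discharged_7d", "discharged_30d", "hosp_days_prior_year",
                "admissions_prior_year", "ae_attendances_prior_year", "ae_30d", "abx_30d",
                "home_visit", "exposure", "delayed_rx"]
    key = ["patient_id", "start_date"]
    # compare exactly the episodes whose history was perturbed after their
    # start (later episodes of the same patient may legitimately change)
    merged = extra.merge(rows[key + cov_cols], on=key).merge(
        rows2[key + cov_cols], on=key, suffixes=("_a", "_b")
    )
    assert len(merged) == len(extra)
    for c in cov_cols:
        assert (merged[f"{c}_a"] == merged[f"{c}_b"]).all(), c
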