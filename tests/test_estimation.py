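"""GEE estimation, screening, interactions, NNEH and sensitivity variants."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from uti_episodes import (
    average_risk_difference_nneh,
    fit_final_model,
    fit_gee_logit,
    fit_interactions,
    run_sensitivity,
    screen_univariable,
    segment_uti_episodes,
)
from uti_episodes.estimation import EXPOSURE
from uti_episodes.reporting import crude_or_2x2


def test_single_episode_per_patient_equals_plain_logistic(null_rows):
    # exchangeable working correlation collapses to independence when every
    # cluster has size one
    one = (
        null_rows.sort_values(["patient_id", "start_date"])
        .groupby("patient_id", as_index=False, observed=True)
        .head(1)
        .reset_index(drop=True)
    )
    terms = ["not_immediate", "female", "age_per5", "home_visit"]
    f = fit_gee_logit(one, "bsi_60", terms)
    X = sm.add_constant(one[terms].astype(float))
    r = sm.Logit(one["bsi_60"].astype(float), X).fit(disp=0)
    gee = {t.name: t.estimate for t in f.terms}
    assert abs(gee["Intercept"] - r.params["const"]) < 1e-4
    for t in terms:
        assert abs(gee[t] - r.params[t]) < 1e-4


def test_saturated_exposure_model_reproduces_contingency_or(null_rows):
    one = null_rows.groupby("patient_id", as_index=False, observed=True).head(1)
    f = fit_gee_logit(one, "bsi_60", [EXPOSURE])
    a = int(((one[EXPOSURE] == 1) & (one["bsi_60"] == 1)).sum())
    b = int(((one[EXPOSURE] == 1) & (one["bsi_60"] == 0)).sum())
    c = int(((one[EXPOSURE] == 0) & (one["bsi_60"] == 1)).sum())
    d = int(((one[EXPOSURE] == 0) & (one["bsi_60"] == 0)).sum())
    expected = crude_or_2x2(a, b, c, d)["or"]
    assert f.exposure_or() == pytest.approx(expected, rel=1e-6)


def test_gee_requires_two_clusters(null_rows):
    single = null_rows[null_rows["patient_id"] == null_rows["patient_id"].iloc[0]]
    with pytest.raises(ValueError, match="clusters"):
        fit_gee_logit(single, "bsi_60", [EXPOSURE])


def test_screen_selection_agrees_with_reported_pvalues(confounded_rows):
    selected, pvals = screen_univariable(confounded_rows, return_pvalues=True)
    expected = [v for v, p in pvals.items() if p == p and p < 0.2]
    assert selected == expected
    assert "female" in selected  # a strong generative confounder


def test_screen_operating_characteristics_under_the_null():
    # a pure-noise covariate should pass the p < 0.2 screen in roughly 20%
    # of null datasets (binomial 95% band around 0.2 for 150 runs)
    rng = np.random.default_rng(1234)
    hits = 0
    n_runs, n = 150, 400
    for _ in range(n_runs):
        df = pd.DataFrame({
            "patient_id": np.arange(n),
            "bsi_60": rng.binomial(1, 0.2, n),
            "noise": rng.normal(size=n),
        })
        sel = screen_univariable(df, candidates=["noise"], outcome="bsi_60")
        hits += "noise" in sel
    assert 0.2 * n_runs - 2.5 * math.sqrt(n_runs * 0.2 * 0.8) <= hits \
        <= 0.2 * n_runs + 2.5 * math.sqrt(n_runs * 0.2 * 0.8)


def test_final_model_forces_exposure_and_composes_screen(confounded_rows):
    f = fit_final_model(confounded_rows)
    names = [t.name for t in f.terms]
    assert EXPOSURE in names
    assert f.converged
    assert f.selected_terms == screen_univariable(confounded_rows)


def test_no_covariate_passing_screen_gives_univariable_model():
    rng = np.random.default_rng(7)
    n = 600
    df = pd.DataFrame({
        "patient_id": np.arange(n),
        "bsi_60": rng.binomial(1, 0.2, n),
        EXPOSURE: rng.binomial(1, 0.5, n),
        "noise": rng.normal(size=n),
    })
    # use a tiny alpha so nothing passes
    f = fit_final_model(df, candidates=["noise"], alpha=1e-6)
    assert [t.name for t in f.terms] == ["Intercept", EXPOSURE]


def test_interaction_requires_varying_modifier(null_rows):
    frozen = null_rows.copy()
    frozen["female"] = 1
    with pytest.raises(ValueError, match="constant"):
        fit_interactions(frozen, "gender")


def test_gender_interaction_returns_product_term_and_strata(harmful_rows):
    inter, strata = fit_interactions(harmful_rows, "gender")
    assert any(":" in t.name for t in inter.terms)
    assert set(strata) == {"female", "male"}
    for f in strata.values():
        assert f.term(EXPOSURE)


def test_nneh_internal_consistency(harmful_rows):
    f = fit_final_model(harmful_rows)
    nn = average_risk_difference_nneh(f, harmful_rows, n_boot=20, seed=3)
    assert nn.nneh_point * nn.ard == pytest.approx(1.0, abs=1e-12)
    assert nn.resample_unit == "patient"
    assert nn.ard_ci[0] <= nn.ard <= nn.ard_ci[1]


def test_nneh_zero_coefficient_gives_infinite_nneh():
    # perfectly balanced outcome within exposure groups: the exposure
    # coefficient is exactly zero and the risk difference map is null
    df = pd.DataFrame({
        "patient_id": np.arange(40),
        EXPOSURE: [0, 1] * 20,
        "bsi_60": [0, 0, 1, 1] * 10,
    })
    f = fit_gee_logit(df, "bsi_60", [EXPOSURE])
    assert abs(f.term(EXPOSURE).estimate) < 1e-12
    nn = average_risk_difference_nneh(f, df, n_boot=0, seed=0)
    assert nn.infinite
    assert math.isinf(nn.nneh_point)


def test_nneh_hand_oracle_on_four_rows(harmful_rows):
    # standardisation arithmetic: ARD must equal the hand-computed mean of
    # per-row risk differences under the fitted coefficients
    f = fit_gee_logit(harmful_rows, "bsi_60", [EXPOSURE, "female"])
    b = {t.name: t.estimate for t in f.terms}
    four = harmful_rows.head(4)
    expit = lambda x: 1 / (1 + math.exp(-x))
    expected = np.mean([
        expit(b["Intercept"] + b[EXPOSURE] + b["female"] * r.female)
        - expit(b["Intercept"] + b["female"] * r.female)
        for r in four.itertuples()
    ])
    from uti_episodes.estimation import _ard_from_result

    assert _ard_from_result(f.model_result, four) == pytest.approx(expected, abs=1e-9)


def test_first_episode_sensitivity_counts_patients(harmful_bundle, harmful_rows):
    sc, b = harmful_bundle
    f = run_sensitivity(b, sc.study_start, sc.study_end, "first_episode_only")
    assert f.n_obs == harmful_rows["patient_id"].nunique()
    assert f.n_clusters == f.n_obs


def test_window30_segmentation_splits_45_day_gap():
    eps = segment_uti_episodes([0, 45], window_days=30)
    assert [e.status for e in eps] == ["analyzed", "analyzed"]
    assert [e.member_dates for e in eps] == [(0,), (45,)]


def test_unknown_sensitivity_variant_errors(harmful_bundle):
    sc, b = harmful_bundle
    with pytest.raises(ValueError, match="variant"):
        run_sensitivity(b, sc.study_start, sc.study_end, "bogus")
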