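"""Episode segmentation state machine and community-onset filters.

The brute-force oracle exploits that, scanning sorted dates, the "last
evidence" is always simply the previous date (members, ongoing codes and
new starts all refresh it) — so the classifier reduces to two comparisons
per date, implemented independently of the production state machine.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from uti_episodes import segment_uti_episodes, apply_onset_filters, build_episodes
from uti_episodes.episodes import UTIEpisode
from uti_episodes.cohort import compute_cohort


def brute_force_classify(dates, window=60):
    """Independent oracle: per-date labels 'start' / 'member' / 'ongoing'."""
    labels = []
    start = None
    for i, d in enumerate(dates):
        if i == 0:
            labels.append("start")
            start = d
        elif d - start <= window:
            labels.append("member")
        elif d - dates[i - 1] > window:
            labels.append("start")
            start = d
        else:
            labels.append("ongoing")
    return labels


def flatten(episodes):
    labels = {}
    for e in episodes:
        if e.status == "excluded_ongoing":
            labels[e.start_date] = "ongoing"
        else:
            labels[e.member_dates[0]] = "start"
            for d in e.member_dates[1:]:
                labels[d] = "member"
    return labels


def test_two_codes_within_window_then_clear_gap_yields_two_episodes():
    eps = segment_uti_episodes([0, 30, 95])
    analyzed = [e for e in eps if e.status == "analyzed"]
    assert len(analyzed) == 2
    assert analyzed[0].member_dates == (0, 30)
    assert analyzed[1].member_dates == (95,)
    assert analyzed[1].episode_index == 2


def test_late_code_close_to_last_evidence_is_ongoing_and_excluded():
    eps = segment_uti_episodes([0, 45, 95])
    analyzed = [e for e in eps if e.status == "analyzed"]
    ongoing = [e for e in eps if e.status == "excluded_ongoing"]
    assert len(analyzed) == 1 and analyzed[0].member_dates == (0, 45)
    assert len(ongoing) == 1 and ongoing[0].start_date == 95


def test_singleton_code_is_one_episode():
    eps = segment_uti_episodes([0])
    assert len(eps) == 1
    assert eps[0].member_dates == (0,)


def test_window_boundary_is_inclusive():
    assert len(segment_uti_episodes([0, 60])) == 1
    two = segment_uti_episodes([0, 61])
    assert [e.status for e in two] == ["analyzed", "analyzed"]


def test_ongoing_code_keeps_blocking_until_a_clear_gap():
    # 0-45 one episode; 95 ongoing; 140 still within 60 of 95 -> ongoing;
    # 210 is > 60 past 140 -> new episode
    eps = segment_uti_episodes([0, 45, 95, 140, 210])
    statuses = [(e.start_date, e.status) for e in eps]
    assert statuses == [
        (0, "analyzed"), (95, "excluded_ongoing"),
        (140, "excluded_ongoing"), (210, "analyzed"),
    ]


def test_unsorted_dates_raise():
    with pytest.raises(ValueError, match="ascending"):
        segment_uti_episodes([10, 5])


@given(
    st.lists(st.integers(min_value=0, max_value=400), min_size=1, max_size=8, unique=True)
)
@settings(max_examples=300, deadline=None)
def test_state_machine_matches_brute_force_oracle(days):
    days = sorted(days)
    eps = segment_uti_episodes(days)
    assert flatten(eps) == dict(zip(days, brute_force_classify(days)))


@given(
    st.lists(st.integers(min_value=0, max_value=200), min_size=1, max_size=6, unique=True),
    st.sampled_from([30, 60]),
)
@settings(max_examples=200, deadline=None)
def test_partition_property_every_date_classified_once(days, window):
    days = sorted(days)
    eps = segment_uti_episodes(days, window_days=window)
    n_members = sum(len(e.member_dates) for e in eps if e.status != "excluded_ongoing")
    n_ongoing = sum(1 for e in eps if e.status == "excluded_ongoing")
    assert n_members + n_ongoing == len(days)
    starts = [e.start_date for e in eps if e.status != "excluded_ongoing"]
    assert all(b - a > window for a, b in zip(starts, starts[1:]))


def _episode(start=100):
    return UTIEpisode(1, start, (start,), "analyzed", "", 1)


COHORT_OK = {"eligible": True, "entry_date": 0, "exit_date": 1000}


def test_same_day_ae_excludes_with_reason():
    out = apply_onset_filters(_episode(), {"ae": True}, [], COHORT_OK)
    assert out.status == "excluded_same_day_event"
    assert out.exclusion_detail == "ae"


def test_same_day_precedence_admission_beats_in_hospital():
    out = apply_onset_filters(_episode(100), {"admission": True}, [(100, 110)], COHORT_OK)
    assert out.status == "excluded_same_day_event"
    assert out.exclusion_detail == "admission"


def test_start_inside_spell_is_in_hospital_discharge_day_inclusive():
    for day in (95, 100, 105):
        out = apply_onset_filters(_episode(day), {}, [(95, 105)], COHORT_OK)
        assert out.status == "excluded_in_hospital", day
    out = apply_onset_filters(_episode(106), {}, [(95, 105)], COHORT_OK)
    assert out.status == "analyzed"


def test_start_outside_cohort_interval_is_excluded():
    out = apply_onset_filters(_episode(100), {}, [], {"eligible": True, "entry_date": 200, "exit_date": 900})
    assert out.status == "excluded_outside_cohort"


def test_clean_episode_passes_through():
    out = apply_onset_filters(_episode(), {}, [(300, 310)], COHORT_OK)
    assert out.status == "analyzed"


def test_global_partition_invariant_on_synthetic_run(null_bundle):
    sc, b = null_bundle
    cohort = compute_cohort(b.patients, sc.study_start, sc.study_end)
    eps = build_episodes(b, cohort)
    from uti_episodes.episodes import _uti_code_dates

    n_codes = len(_uti_code_dates(b))
    n_members = eps.loc[eps["status"] != "excluded_ongoing", "n_member_codes"].sum()
    n_ongoing = (eps["status"] == "excluded_ongoing").sum()
    assert n_members + n_ongoing == n_codes
    assert set(eps["status"]) <= {
        "analyzed", "excluded_ongoing", "excluded_same_day_event",
        "excluded_in_hospital", "excluded_outside_cohort",
    }


def test_analyzed_episode_starts_lie_inside_cohort_interval(null_rows, null_bundle):
    sc, b = null_bundle
    cohort = compute_cohort(b.patients, sc.study_start, sc.study_end).set_index("patient_id")
    starts = null_rows.set_index("patient_id")["start_date"]
    for pid, s in starts.items():
        assert cohort.at[pid, "entry"] <= s <= cohort.at[pid, "exit"]
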