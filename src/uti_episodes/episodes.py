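"""Segmentation of coded UTI evidence into new versus ongoing episodes.

The first UTI code opens an episode; any code within ``window_days``
(default 60, inclusive) of the episode start belongs to that episode and
updates the "last evidence" marker.  A code more than ``window_days`` after
the start opens a *new* episode only if it is also more than ``window_days``
after the last evidence; otherwise it is flagged as an ongoing episode and
excluded from analysis, while still blocking later codes until a clear gap
has elapsed.

Community-onset filters then exclude episodes with a same-day hospital
admission, A&E attendance, specialist referral or death; episodes starting
while the patient was in hospital (admission and discharge day inclusive);
and episodes starting outside the patient's at-risk interval.  Filters apply
in that order so each exclusion carries exactly one reason.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

DEFAULT_WINDOW_DAYS = 60

STATUSES = (
    "analyzed",
    "excluded_ongoing",
    "excluded_same_day_event",
    "excluded_in_hospital",
    "excluded_outside_cohort",
)
#: same-day exclusion reasons, in precedence order
SAME_DAY_REASONS = ("admission", "ae", "referral", "death")


@dataclass(frozen=True)
class UTIEpisode:
    patient_id: int | None
    start_date: object                 # date-like or int day offset
    member_dates: tuple
    status: str
    exclusion_detail: str = ""
    episode_index: int | None = None   # ordinal among non-ongoing episodes


def _days(a, b) -> float:
    """a - b in days, for ints, dates or Timestamps."""
    diff = a - b
    return diff.days if hasattr(diff, "days") else diff


def segment_uti_episodes(
    uti_dates: Sequence,
    window_days: int = DEFAULT_WINDOW_DAYS,
    patient_id: int | None = None,
) -> list[UTIEpisode]:
    """Scan one patient's deduplicated, ascending UTI code dates.

    Returns episodes (provisional status ``analyzed``) interleaved with
    ``excluded_ongoing`` records, preserving date order.  Every input date
    appears in exactly one episode's ``member_dates`` or in exactly one
    ongoing-exclusion record.
    """
    out: list[UTIEpisode] = []
    if len(uti_dates) == 0:
        return out
    for a, b in zip(uti_dates, uti_dates[1:]):
        if _days(b, a) <= 0:
            raise ValueError("uti_dates must be strictly ascending (deduplicated per day)")

    idx = 0
    current_start = None
    members: list = []
    last_evidence = None

    def close_current():
        nonlocal idx
        if current_start is not None:
            idx += 1
            out.append(
                UTIEpisode(patient_id, current_start, tuple(members), "analyzed",
                           "", idx)
            )

    for d in uti_dates:
        if current_start is None:
            current_start, members, last_evidence = d, [d], d
            continue
        if _days(d, current_start) <= window_days:
            members.append(d)
            last_evidence = d
        elif _days(d, last_evidence) > window_days:
            close_current()
            current_start, members, last_evidence = d, [d], d
        else:
            # ongoing evidence: excluded, but keeps blocking new starts
            out.append(UTIEpisode(patient_id, d, (d,), "excluded_ongoing", "", None))
            last_evidence = d
    close_current()
    out.sort(key=lambda e: (_days(e.start_date, uti_dates[0]),))
    return out


def apply_onset_filters(
    episode: UTIEpisode,
    same_day: dict,
    spells: Sequence[tuple],
    cohort_interval,
) -> UTIEpisode:
    """Resolve an episode's final status from its start-date context.

    ``same_day`` maps reason -> bool for admission / ae / referral / death on
    the start date; ``spells`` is a sequence of (admission, discharge) pairs
    (closed interval — the discharge day counts as in-hospital);
    ``cohort_interval`` exposes ``entry_date``/``exit_date``/``eligible`` or
    equivalent mapping keys.
    """
    if episode.status != "analyzed":
        return episode
    s = episode.start_date
    for reason in SAME_DAY_REASONS:
        if same_day.get(reason, False):
            return replace(episode, status="excluded_same_day_event", exclusion_detail=reason)
    for adm, dis in spells:
        if _days(s, adm) >= 0 and _days(dis, s) >= 0:
            return replace(episode, status="excluded_in_hospital", exclusion_detail="in_hospital")
    if hasattr(cohort_interval, "eligible"):
        eligible = cohort_interval.eligible
        entry, exit_ = cohort_interval.entry_date, cohort_interval.exit_date
    else:
        eligible = cohort_interval.get("eligible", True)
        entry, exit_ = cohort_interval["entry_date"], cohort_interval["exit_date"]
    if not eligible:
        return replace(episode, status="excluded_outside_cohort", exclusion_detail="")
    if _days(s, entry) < 0 or _days(exit_, s) < 0:
        return replace(episode, status="excluded_outside_cohort", exclusion_detail="")
    return episode


def _uti_code_dates(bundle) -> pd.DataFrame:
    """All UTI evidence dates (primary-care events and hospital diagnoses)."""
    ev = bundle.events
    pc = ev.loc[ev["category"] == "uti", ["patient_id", "event_date"]]
    sp = bundle.spells
    hx = sp.loc[sp["category"] == "uti", ["patient_id", "admission_date"]].rename(
        columns={"admission_date": "event_date"}
    )
    dates = pd.concat([pc, hx], ignore_index=True).drop_duplicates()
    return dates.sort_values(["patient_id", "event_date"])


def build_episodes(
    bundle, cohort: pd.DataFrame, window_days: int = DEFAULT_WINDOW_DAYS
) -> pd.DataFrame:
    """Segment and filter every patient's UTI evidence.

    Returns one row per episode or ongoing-exclusion record with columns
    ``patient_id, episode_index, start, status, exclusion_detail,
    n_member_codes``.
    """
    dates = _uti_code_dates(bundle)

    ev = bundle.events
    referrals = ev.loc[ev["category"] == "referral"]
    referral_set = set(zip(referrals["patient_id"], referrals["event_date"]))
    ae_set = set(zip(bundle.ae["patient_id"], bundle.ae["attendance_date"]))
    death_map = dict(zip(bundle.deaths["patient_id"], bundle.deaths["death_date"]))

    sp = bundle.spells.drop_duplicates(subset=["patient_id", "spell_id"])
    spells_by_pid: dict[int, list[tuple]] = {}
    for pid, adm, dis in zip(sp["patient_id"], sp["admission_date"], sp["discharge_date"]):
        spells_by_pid.setdefault(pid, []).append((adm, dis))

    chz = cohort.set_index("patient_id")

    rows = []
    for pid, grp in dates.groupby("patient_id", sort=True):
        eps = segment_uti_episodes(
            list(grp["event_date"]), window_days=window_days, patient_id=pid
        )
        pid_spells = spells_by_pid.get(pid, [])
        adm_days = {a for a, _ in pid_spells}
        if pid in chz.index:
            ci = {
                "eligible": bool(chz.at[pid, "eligible"]),
                "entry_date": chz.at[pid, "entry"],
                "exit_date": chz.at[pid, "exit"],
            }
        else:
            ci = {"eligible": False, "entry_date": pd.NaT, "exit_date": pd.NaT}
        for e in eps:
            if e.status == "analyzed":
                s = e.start_date
                same_day = {
                    "admission": s in adm_days,
                    "ae": (pid, s) in ae_set,
                    "referral": (pid, s) in referral_set,
                    "death": death_map.get(pid) == s,
                }
                e = apply_onset_filters(e, same_day, pid_spells, ci)
            rows.append(
                (pid, e.episode_index, e.start_date, e.status, e.exclusion_detail,
                 len(e.member_dates) if e.status != "excluded_ongoing" else 0)
            )
    out = pd.DataFrame(
        rows,
        columns=["patient_id", "episode_index", "start", "status",
                 "exclusion_detail", "n_member_codes"],
    )
    out["episode_index"] = out["episode_index"].astype("Int64")
    return out
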