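"""Synthetic linked primary-care / hospital / death data with known ground truth.

Emulates the structure of CPRD (primary-care events and prescriptions) linked
to HES (hospital spells with ordered coded diagnoses, A&E attendances) and
ONS death registration, for a population aged >=65.  The generator produces
repeated UTI consultations clustered within patients, same-day antibiotic
prescribing whose probability depends on measured covariates (confounding by
indication), rare bloodstream-infection (BSI) outcomes realised as coded
sepsis diagnoses in hospital or primary care, deaths, background
hospitalisations and A&E attendances, and the covariate structure used by
the analysis (home visits, prior antibiotics, Charlson comorbidity, smoking,
recurrent UTI).

Every patient draws from an independent random substream keyed on
``(seed, patient_id)``, so enlarging the cohort never perturbs existing
patients' histories.  All dates are day-granular.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from uti_episodes.codelist import charlson_weights

_EPOCH = date(1970, 1, 1)

REGIONS = (
    "South of England",
    "London",
    "Midlands and East of England",
    "North of England and Yorkshire",
)
_REGION_CUM = np.cumsum([0.41, 0.10, 0.28, 0.21])
_IMD_CUM = np.cumsum([0.25, 0.24, 0.22, 0.17, 0.12])

#: Covariates that may carry confounding effects, as they are realised at
#: each UTI consultation.  ``age_per5_c`` is (age - 77.5) / 5.
CONFOUNDER_KEYS = ("home_visit", "prior_abx_30d", "female", "age_per5_c", "cci")

_UTI_ABX = ("trimethoprim", "nitrofurantoin", "amoxicillin", "cefalexin")
_BG_ABX = ("amoxicillin", "flucloxacillin", "doxycycline", "clarithromycin")

_CCI_CODES = {
    "myocardial_infarction": "PC-CCI-MI-01",
    "congestive_heart_failure": "PC-CCI-CHF-01",
    "peripheral_vascular_disease": "PC-CCI-PVD-01",
    "cerebrovascular_disease": "PC-CCI-CVD-01",
    "dementia": "PC-CCI-DEM-01",
    "chronic_pulmonary_disease": "PC-CCI-COPD-01",
    "rheumatologic_disease": "PC-CCI-RHEUM-01",
    "peptic_ulcer_disease": "PC-CCI-PUD-01",
    "mild_liver_disease": "PC-CCI-LIVM-01",
    "diabetes": "PC-CCI-DIAB-01",
    "diabetes_complications": "PC-CCI-DIABC-01",
    "hemiplegia": "PC-CCI-PLEG-01",
    "renal_disease": "PC-CCI-RENAL-01",
    "malignancy": "PC-CCI-CANC-01",
    "severe_liver_disease": "PC-CCI-LIVS-01",
    "metastatic_tumour": "PC-CCI-METS-01",
    "aids": "PC-CCI-AIDS-01",
}
_CCI_GROUPS = tuple(_CCI_CODES)


def _d(x: date) -> int:
    return (x - _EPOCH).days


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _expit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


@dataclass(frozen=True)
class ConfounderEffect:
    """Log-odds contributions of one covariate.

    ``on_assignment`` shifts the log-odds that an episode is *not* treated
    immediately; ``on_outcome`` shifts the log-odds of BSI within 60 days.
    """

    on_assignment: float = 0.0
    on_outcome: float = 0.0


@dataclass(frozen=True)
class EffectScenario:
    """Generative parameters for one simulated study.

    The scenario fixes both the nuisance structure (consultation rates,
    background utilisation, demographics) and the estimand-relevant ground
    truth: the exposure odds ratio for BSI and the per-covariate confounding
    effects that act on treatment assignment and outcome simultaneously.
    """

    name: str = "custom"
    n_patients: int = 1000
    study_start: date = date(2007, 4, 1)
    study_end: date = date(2015, 3, 31)
    baseline_bsi_risk: float = 0.004
    true_exposure_or: float = 1.0
    confounder_effects: dict[str, ConfounderEffect] = field(default_factory=dict)
    uti_rate: float = 0.0757          # UTI episodes per patient-year (population marginal)
    recurrence_dispersion: float = 0.8  # variance of the gamma frailty on the UTI rate
    prescribe_prob_base: float = 0.873  # P(immediate) at reference covariates
    delayed_prob: float = 0.181         # P(day 1-7 prescription | not immediate)
    mortality_rate: float = 0.055       # background deaths per patient-year
    hospitalization_rate: float = 0.22  # background admissions per patient-year
    ae_rate: float = 0.30               # background A&E attendances per patient-year
    abx_rate: float = 2.2               # background antibiotic scripts per patient-year
    female_prob: float = 0.60
    female_uti_rate_ratio: float = 2.30
    home_visit_prob: float = 0.045
    bsi_frailty_sd: float = 0.4         # patient-level normal frailty on BSI log-odds
    hospital_confirm_prob: float = 0.70
    death_after_bsi_prob: float = 0.15
    base_death_60: float = 0.012        # episode-level extra 60-day death probability
    mortality_exposure_or: float = 1.0
    imd_missing_prob: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.study_start >= self.study_end:
            raise ValueError("study_start must precede study_end")
        for nm in ("baseline_bsi_risk", "prescribe_prob_base", "delayed_prob",
                   "female_prob", "home_visit_prob", "hospital_confirm_prob",
                   "death_after_bsi_prob", "base_death_60", "imd_missing_prob"):
            v = getattr(self, nm)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{nm} must lie in [0, 1], got {v}")
        if self.true_exposure_or <= 0 or self.mortality_exposure_or <= 0:
            raise ValueError("true_exposure_or and mortality_exposure_or must be positive")
        for nm in ("uti_rate", "recurrence_dispersion", "mortality_rate",
                   "hospitalization_rate", "ae_rate", "abx_rate",
                   "female_uti_rate_ratio", "bsi_frailty_sd"):
            if getattr(self, nm) < 0:
                raise ValueError(f"{nm} must be >= 0")
        bad = set(self.confounder_effects) - set(CONFOUNDER_KEYS)
        if bad:
            raise ValueError(
                f"unknown confounder keys {sorted(bad)}; known: {CONFOUNDER_KEYS}"
            )

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["study_start"] = self.study_start.isoformat()
        d["study_end"] = self.study_end.isoformat()
        d["confounder_effects"] = {
            k: {"on_assignment": v.on_assignment, "on_outcome": v.on_outcome}
            for k, v in self.confounder_effects.items()
        }
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EffectScenario":
        d = yaml.safe_load(Path(path).read_text())
        d["study_start"] = date.fromisoformat(d["study_start"])
        d["study_end"] = date.fromisoformat(d["study_end"])
        d["confounder_effects"] = {
            k: ConfounderEffect(**v) for k, v in d.get("confounder_effects", {}).items()
        }
        sc = cls(**d)
        sc.validate()
        return sc


_PRESETS: dict[str, dict] = {
    # Pure null: no exposure effect, no confounding.  Elevated episode and
    # outcome rates over a 3-year window keep replicate simulations cheap
    # while leaving hundreds of events per run.
    "null_effect": dict(
        name="null_effect",
        study_end=date(2010, 3, 31),
        baseline_bsi_risk=0.05,
        true_exposure_or=1.0,
        confounder_effects={},
        uti_rate=0.50,
        recurrence_dispersion=0.5,
        prescribe_prob_base=0.85,
        bsi_frailty_sd=0.4,
        base_death_60=0.012,
    ),
    # Null exposure effect with strong confounding by indication: home
    # visits, recent antibiotics, gender, age and comorbidity all push both
    # treatment withholding and BSI in directions mirroring the study's
    # Table-1 imbalances, so the crude OR is biased well above 1.
    "confounded_null": dict(
        name="confounded_null",
        study_end=date(2010, 3, 31),
        baseline_bsi_risk=0.10,
        true_exposure_or=1.0,
        # confounding concentrated on the outcome side: the crude bias is
        # the product of the two arms, while propensity-weight tails are
        # driven by the assignment side alone
        confounder_effects={
            "home_visit": ConfounderEffect(1.6, 2.0),
            "prior_abx_30d": ConfounderEffect(0.8, 1.1),
            "female": ConfounderEffect(-1.2, -1.5),
            "age_per5_c": ConfounderEffect(0.12, 0.45),
            "cci": ConfounderEffect(0.10, 0.35),
        },
        uti_rate=0.50,
        recurrence_dispersion=0.5,
        prescribe_prob_base=0.87,
        bsi_frailty_sd=0.4,
    ),
    # A genuinely harmful delay (OR 1.5 for BSI, 1.3 for death) with mild
    # confounding in the same directions.
    "harmful_delay": dict(
        name="harmful_delay",
        study_end=date(2010, 3, 31),
        baseline_bsi_risk=0.05,
        true_exposure_or=1.5,
        confounder_effects={
            "home_visit": ConfounderEffect(0.9, 0.7),
            "prior_abx_30d": ConfounderEffect(0.5, 0.4),
            "female": ConfounderEffect(-0.8, -0.5),
        },
        uti_rate=0.50,
        recurrence_dispersion=0.5,
        prescribe_prob_base=0.86,
        mortality_exposure_or=1.3,
        # no patient-level outcome frailty: the generative exposure OR is
        # then also the population-averaged contrast the GEE estimates
        bsi_frailty_sd=0.0,
    ),
    # Calibrated to the study's Table-1 marginals over the full 2007-2015
    # window: ~87.3% immediate prescribing, ~77.5% of episodes in women,
    # ~0.45% BSI per episode, ~18% delayed prescriptions among the
    # not-immediate group.  Confounding directions mirror Table 1.
    "table1_calibrated": dict(
        name="table1_calibrated",
        baseline_bsi_risk=0.0040,
        true_exposure_or=1.1,
        confounder_effects={
            "home_visit": ConfounderEffect(1.15, 0.9),
            "prior_abx_30d": ConfounderEffect(0.65, 0.35),
            "female": ConfounderEffect(-1.05, -0.60),
            "age_per5_c": ConfounderEffect(0.06, 0.20),
            "cci": ConfounderEffect(0.03, 0.15),
        },
        uti_rate=0.082,
        recurrence_dispersion=0.8,
        prescribe_prob_base=0.815,
        delayed_prob=0.12,
        abx_rate=2.7,
        home_visit_prob=0.044,
        female_uti_rate_ratio=2.38,
        bsi_frailty_sd=0.4,
        base_death_60=0.012,
        mortality_exposure_or=1.4,
    ),
}


def scenario_presets(name: str, **overrides) -> EffectScenario:
    """Return a named, fully populated scenario.

    ``overrides`` (e.g. ``n_patients`` or ``seed``) replace preset fields.
    """
    if name not in _PRESETS:
        raise ValueError(
            f"unknown scenario preset {name!r}; available: {sorted(_PRESETS)}"
        )
    params = dict(_PRESETS[name])
    params.update(overrides)
    sc = EffectScenario(**params)
    sc.validate()
    return sc


# ---------------------------------------------------------------------------
# Table bundle


_SCHEMA: dict[str, dict[str, str]] = {
    "patients": {
        "patient_id": "int", "gender": "str", "birth_date": "date",
        "death_date": "date", "practice_id": "int", "region": "str",
        "imd_quintile": "Int64", "registration_start": "date",
        "registration_end": "date", "up_to_standard_date": "date",
        "last_collection_date": "date",
    },
    "events": {
        "patient_id": "int", "event_date": "date", "setting": "str",
        "code": "str", "category": "str", "subcategory": "str",
        "home_visit": "int",
    },
    "prescriptions": {
        "patient_id": "int", "issue_date": "date",
        "is_systemic_antibiotic": "int", "substance": "str",
        "duration_days": "Int64",
    },
    "spells": {
        "patient_id": "int", "spell_id": "int", "admission_date": "date",
        "discharge_date": "date", "position": "int", "code": "str",
        "category": "str", "subcategory": "str",
    },
    "ae": {"patient_id": "int", "attendance_date": "date"},
    "deaths": {"patient_id": "int", "death_date": "date"},
}


@dataclass
class TableBundle:
    """The six linked tables of one simulated study."""

    patients: pd.DataFrame
    events: pd.DataFrame
    prescriptions: pd.DataFrame
    spells: pd.DataFrame
    ae: pd.DataFrame
    deaths: pd.DataFrame
    #: generator ground truth (one row per community-onset episode with its
    #: assigned exposure and latent outcome); never written by emit_tables
    truth: pd.DataFrame | None = None

    def tables(self) -> dict[str, pd.DataFrame]:
        return {name: getattr(self, name) for name in _SCHEMA}


def _coerce(df: pd.DataFrame, table: str) -> pd.DataFrame:
    schema = _SCHEMA[table]
    out = pd.DataFrame(index=df.index if len(df) else None)
    for col, kind in schema.items():
        s = df[col] if col in df.columns else pd.Series([], dtype=object)
        if kind == "date":
            out[col] = pd.to_datetime(s, errors="coerce")
        elif kind == "int":
            out[col] = pd.to_numeric(s, errors="raise").astype("int64")
        elif kind == "Int64":
            out[col] = pd.to_numeric(s, errors="coerce").astype("Int64")
        else:
            vals = pd.Series(s, dtype=object).where(pd.notna(s), "")
            out[col] = vals.astype(str).replace("nan", "")
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Generation


def _patient_region(practice_id: int) -> str:
    # Deterministic hash of the practice id onto the regional distribution,
    # independent of any random stream.
    u = ((practice_id * 2654435761) % 4294967296) / 4294967296.0
    return REGIONS[int(np.searchsorted(_REGION_CUM, u))]


def _simulate_patient(pid: int, sc: EffectScenario, seed: int, weights: dict[str, int],
                      rows: dict[str, list]) -> None:
    rng = np.random.default_rng([seed, pid])
    s0, s1 = _d(sc.study_start), _d(sc.study_end)

    female = rng.random() < sc.female_prob
    age0 = rng.uniform(58.0, 88.0)
    birth = s0 - int(age0 * 365.25)
    if rng.random() < 0.08:
        reg_start = s0 + int(rng.uniform(0, 4) * 365.25)
    else:
        reg_start = s0 - int(rng.uniform(1.5, 25.0) * 365.25)
    uts = reg_start + (int(rng.uniform(0, 1.5) * 365.25) if rng.random() < 0.3 else 0)
    last_coll = s1 if rng.random() < 0.85 else s1 - int(rng.uniform(0, 3) * 365.25)
    if rng.random() < 0.10:
        reg_end = reg_start + int(rng.uniform(1, 12) * 365.25)
    else:
        reg_end = s1 + 365
    reg_end = max(reg_end, reg_start + 30)
    admin_end = min(reg_end, last_coll)

    practice_id = (pid - 1) // 50 + 1  # fixed practice size, independent of cohort size
    region = _patient_region(practice_id)
    imd = None if rng.random() < sc.imd_missing_prob else int(np.searchsorted(_IMD_CUM, rng.random())) + 1

    if admin_end <= reg_start + 1:
        # registry row with no observable window (late registration with an
        # earlier practice collection stop): nothing can be recorded
        rows["patients"].append((
            pid, "female" if female else "male", birth, None, practice_id,
            region, imd, reg_start, reg_end, uts, last_coll,
        ))
        return

    death_cand = math.inf
    if sc.mortality_rate > 0:
        death_cand = max(s0, reg_start) + rng.exponential(1.0 / sc.mortality_rate) * 365.25

    events: list[tuple] = []       # (date, setting, code, category, subcategory, home_visit)
    scripts: list[tuple] = []      # (date, is_abx, substance, duration)
    spells: list[tuple] = []       # (spell_id, adm, dis, position, code, category, subcategory)
    attendances: list[int] = []
    spell_counter = 0

    # --- static history: comorbidities, smoking, recurrent-UTI markers -----
    hist_end = min(admin_end, s0 + 365)
    hist_span = max(30, hist_end - reg_start)
    n_groups = min(int(rng.poisson(1.2)), len(_CCI_GROUPS))
    group_idx = rng.choice(len(_CCI_GROUPS), size=n_groups, replace=False)
    cci_items: list[tuple[int, str]] = []  # (date, group)
    for gi in sorted(group_idx):
        g = _CCI_GROUPS[gi]
        dt = min(reg_start + int(rng.uniform(0, 0.8) * hist_span), admin_end)
        cci_items.append((dt, g))
        events.append((dt, "primary_care", _CCI_CODES[g], f"comorbidity:{g}", "", 0))

    smoke_u = rng.random()
    if smoke_u < 0.07:  # current smoker
        dt = min(reg_start + int(rng.uniform(0, 0.8) * hist_span), admin_end)
        events.append((dt, "primary_care", "PC-SMK-C-01", "smoking_status", "current", 0))
    elif smoke_u < 0.40:  # ex-smoker
        d1 = min(reg_start + int(rng.uniform(0, 0.5) * hist_span), admin_end)
        d2 = min(d1 + max(30, int(rng.uniform(0.1, 0.4) * hist_span)), admin_end)
        events.append((d1, "primary_care", "PC-SMK-C-01", "smoking_status", "current", 0))
        if rng.random() < 0.5:
            events.append((d2, "primary_care", "PC-SMK-X-01", "smoking_status", "ex", 0))
        else:
            # latest code says non-smoker; the derivation must reclassify as ex
            events.append((d2, "primary_care", "PC-SMK-N-01", "smoking_status", "non", 0))

    if rng.random() < 0.04:
        dt = min(reg_start + int(rng.uniform(0, 0.9) * hist_span), admin_end)
        events.append((dt, "primary_care", "PC-RUTI-01", "recurrent_uti", "", 0))
    if rng.random() < 0.03:
        dt = min(reg_start + int(rng.uniform(0, 0.9) * hist_span), admin_end)
        sub = "nitrofurantoin" if rng.random() < 0.5 else "trimethoprim"
        scripts.append((dt, 1, sub, int(rng.integers(28, 57))))

    # --- background utilisation -------------------------------------------
    bg_start = max(reg_start, s0 - 430)
    bg_end = min(admin_end, s1)
    years = max(0.0, (bg_end - bg_start) / 365.25)
    if years > 0:
        for _ in range(rng.poisson(sc.abx_rate * years)):
            dt = int(rng.uniform(bg_start, bg_end))
            scripts.append((dt, 1, _BG_ABX[int(rng.integers(len(_BG_ABX)))], int(rng.integers(5, 8))))
        for _ in range(rng.poisson(sc.hospitalization_rate * years)):
            adm = int(rng.uniform(bg_start, bg_end))
            los = 1 + int(rng.poisson(3))
            spell_counter += 1
            u = rng.random()
            if u < 0.80:
                diag = ("HX-OTH-01", "none", "")
            elif u < 0.93 and cci_items:
                _, g = cci_items[int(rng.integers(len(cci_items)))]
                diag = (_CCI_CODES[g], f"comorbidity:{g}", "")
            else:
                diag = ("HX-INF-RESP-01", "other_infection", "lower_respiratory") if rng.random() < 0.6 \
                    else ("HX-INF-SKIN-01", "other_infection", "other")
            spells.append((spell_counter, adm, adm + los, 1, *diag))
            if rng.random() < 0.3:
                spells.append((spell_counter, adm, adm + los, 2, "HX-OTH-01", "none", ""))
        for _ in range(rng.poisson(sc.ae_rate * years)):
            attendances.append(int(rng.uniform(bg_start, bg_end)))

    # --- UTI episode process ----------------------------------------------
    norm = sc.female_prob * sc.female_uti_rate_ratio + (1.0 - sc.female_prob)
    sex_mult = (sc.female_uti_rate_ratio if female else 1.0) / norm
    if sc.recurrence_dispersion > 0:
        shape = 1.0 / sc.recurrence_dispersion
        frailty = rng.gamma(shape, sc.recurrence_dispersion)
    else:
        frailty = 1.0
    rate = sc.uti_rate * frailty * sex_mult

    onset_lo = max(reg_start + 30, s0 - 120)
    onset_hi = min(admin_end, s1, int(min(death_cand, 10**9)))
    onsets: list[int] = []
    span_years = max(0.0, (onset_hi - onset_lo) / 365.25)
    if rate > 0 and span_years > 0:
        n_onsets = rng.poisson(rate * span_years)
        onsets = sorted(int(rng.uniform(onset_lo, onset_hi)) for _ in range(n_onsets))

    u_bsi = rng.normal(0.0, sc.bsi_frailty_sd) if sc.bsi_frailty_sd > 0 else 0.0
    lp_assign0 = _logit(1.0 - sc.prescribe_prob_base) if sc.prescribe_prob_base < 1.0 else -math.inf
    log_or = math.log(sc.true_exposure_or)
    log_mor = math.log(sc.mortality_exposure_or)

    last_evidence = -(10**9)
    for onset in onsets:
        if onset >= death_cand:
            break
        if onset - last_evidence <= 70:
            continue  # renewal thinning: keep generated episodes separable

        if rng.random() < 0.03:
            # hospital-onset UTI: never analyzable, but its codes block
            # later primary-care codes from opening new episodes
            los = 2 + int(rng.poisson(4))
            spell_counter += 1
            spells.append((spell_counter, onset, onset + los, 1, "HX-UTI-01", "uti", ""))
            last_evidence = onset
            if rng.random() < 0.7:
                fup = onset + int(rng.integers(7, 41))
                if fup < min(admin_end, death_cand):
                    events.append((fup, "primary_care", "PC-UTI-01", "uti", "", 0))
                    last_evidence = fup
            continue

        hv = 1 if rng.random() < sc.home_visit_prob else 0
        truth_rec = None
        prior_abx = int(any(onset - 30 <= dt <= onset - 1 for dt, is_abx, *_ in scripts if is_abx))
        age = (onset - birth) / 365.25
        cci = sum(weights[g] for dt, g in cci_items if dt < onset)
        x = {
            "home_visit": float(hv),
            "prior_abx_30d": float(prior_abx),
            "female": 1.0 if female else 0.0,
            "age_per5_c": (age - 77.5) / 5.0,
            "cci": float(cci),
        }
        conf_a = sum(ce.on_assignment * x[k] for k, ce in sc.confounder_effects.items())
        conf_o = sum(ce.on_outcome * x[k] for k, ce in sc.confounder_effects.items())

        not_imm = rng.random() < _expit(lp_assign0 + conf_a) if lp_assign0 > -math.inf else False
        code = "PC-UTI-01" if rng.random() < 0.6 else ("PC-UTI-02" if rng.random() < 0.5 else "PC-UTI-03")
        events.append((onset, "primary_care", code, "uti", "", hv))
        last_evidence = onset
        if not_imm:
            if rng.random() < sc.delayed_prob:
                dt = onset + int(rng.integers(1, 8))
                if dt <= admin_end:
                    scripts.append((dt, 1, _UTI_ABX[int(rng.integers(len(_UTI_ABX)))], int(rng.integers(3, 8))))
        else:
            scripts.append((onset, 1, _UTI_ABX[int(rng.integers(len(_UTI_ABX)))], int(rng.integers(3, 8))))

        # follow-up UTI codes within the episode window; occasionally a
        # trailing code close enough to the last evidence to count as an
        # ongoing (excluded) episode
        if rng.random() < 0.25:
            extra = onset + int(rng.integers(3, 60))
            if extra < min(admin_end, death_cand):
                events.append((extra, "primary_care", "PC-UTI-03", "uti", "", 0))
                last_evidence = max(last_evidence, extra)
                if extra > onset + 20 and rng.random() < 0.2:
                    tail = onset + 61 + int(rng.integers(0, extra - onset - 2))
                    tail = min(tail, extra + 55)
                    if onset + 60 < tail < min(admin_end, death_cand):
                        events.append((tail, "primary_care", "PC-UTI-03", "uti", "", 0))
                        last_evidence = max(last_evidence, tail)

        # rare same-day events exercising the community-onset filters
        if rng.random() < 0.006:
            events.append((onset, "primary_care", "PC-REF-01", "referral", "", 0))
        if rng.random() < 0.005:
            attendances.append(onset)

        # --- outcome: BSI realised as coded sepsis -------------------------
        p_bsi = _expit(_logit(sc.baseline_bsi_risk) + log_or * not_imm + conf_o + u_bsi) \
            if sc.baseline_bsi_risk > 0 else 0.0
        had_bsi = rng.random() < p_bsi
        truth_rec = [pid, onset, int(not_imm), int(had_bsi), hv, prior_abx,
                     int(female), x["age_per5_c"], float(cci)]
        if had_bsi:
            day = min(60, max(0, int(rng.beta(1.3, 2.2) * 61)))
            bsi_date = onset + day
            if bsi_date < min(admin_end, death_cand) + 1:
                if rng.random() < sc.hospital_confirm_prob:
                    spell_counter += 1
                    los = 3 + int(rng.poisson(8))
                    u = rng.random()
                    if u < 0.41:
                        sep = ("HX-SEP-URO-01", "sepsis", "urosepsis")
                        primary = rng.random() < 0.36
                    elif u < 0.75:
                        if rng.random() < 0.68:
                            sep = ("HX-SEP-RESP-01", "sepsis", "other_infectious:lower_respiratory")
                        else:
                            sep = ("HX-SEP-OTH-01", "sepsis", "other_infectious:other")
                        primary = rng.random() < 0.25
                    else:
                        sep = ("HX-SEP-UNS-01", "sepsis", "unspecified")
                        primary = rng.random() < 0.25
                    if primary:
                        spells.append((spell_counter, bsi_date, bsi_date + los, 1, *sep))
                        spells.append((spell_counter, bsi_date, bsi_date + los, 2, "HX-OTH-01", "none", ""))
                    else:
                        co = ("HX-UTI-01", "uti", "") if (sep[2] == "urosepsis" and rng.random() < 0.4) \
                            else ("HX-OTH-01", "none", "")
                        spells.append((spell_counter, bsi_date, bsi_date + los, 1, *co))
                        spells.append((spell_counter, bsi_date, bsi_date + los, 2, *sep))
                        if co[1] == "uti":
                            last_evidence = max(last_evidence, bsi_date)
                else:
                    events.append((bsi_date, "primary_care", "PC-SEP-01", "sepsis", "unspecified", 0))
                    u = rng.random()
                    if u < 0.80:
                        spell_counter += 1
                        los = 3 + int(rng.poisson(6))
                        if u < 0.63:
                            spells.append((spell_counter, bsi_date, bsi_date + los, 1, "HX-UTI-01", "uti", ""))
                            last_evidence = max(last_evidence, bsi_date)
                        elif u < 0.74:
                            spells.append((spell_counter, bsi_date, bsi_date + los, 1, "HX-INF-RESP-01", "other_infection", "lower_respiratory"))
                        else:
                            spells.append((spell_counter, bsi_date, bsi_date + los, 1, "HX-OTH-01", "none", ""))
                if rng.random() < sc.death_after_bsi_prob:
                    death_cand = min(death_cand, bsi_date + int(rng.integers(0, 21)))

        # episode-level excess mortality (confounded like the outcome)
        if sc.base_death_60 > 0:
            p_d = _expit(_logit(sc.base_death_60) + log_mor * not_imm + 0.25 * conf_o)
            if rng.random() < p_d:
                death_cand = min(death_cand, onset + int(rng.integers(0, 61)))
        if truth_rec is not None:
            rows["truth"].append(tuple(truth_rec))

    # --- finalise: truncate at death, assemble rows ------------------------
    death_day = int(death_cand) if death_cand <= admin_end else None
    cut = death_day if death_day is not None else 10**9

    rows["patients"].append((
        pid, "female" if female else "male", birth, death_day, practice_id,
        region, imd, reg_start, reg_end, uts, last_coll,
    ))
    if death_day is not None:
        rows["deaths"].append((pid, death_day))
    for ev in sorted(events):
        if ev[0] <= cut:
            rows["events"].append((pid, *ev))
    for rx in sorted(scripts):
        if rx[0] <= cut:
            rows["prescriptions"].append((pid, *rx))
    for sp in sorted(spells):
        if sp[1] <= cut:
            dis = min(sp[2], cut)
            rows["spells"].append((pid, sp[0], sp[1], dis, *sp[3:]))
    for at in sorted(attendances):
        if at <= cut:
            rows["ae"].append((pid, at))


def generate_cohort_data(scenario: EffectScenario, seed: int | None = None) -> TableBundle:
    """Simulate the full linked table bundle for one scenario.

    Deterministic: identical ``(scenario, seed)`` pairs reproduce every table
    exactly.  ``seed`` defaults to ``scenario.seed``.
    """
    scenario.validate()
    seed = scenario.seed if seed is None else int(seed)
    weights = charlson_weights()
    rows: dict[str, list] = {name: [] for name in _SCHEMA}
    rows["truth"] = []
    for pid in range(1, scenario.n_patients + 1):
        _simulate_patient(pid, scenario, seed, weights, rows)

    def days_to_ts(s: pd.Series) -> pd.Series:
        v = pd.to_numeric(s, errors="coerce").to_numpy(dtype="float64")
        out = np.full(len(v), np.datetime64("NaT"), dtype="datetime64[D]")
        mask = ~np.isnan(v)
        out[mask] = v[mask].astype(np.int64).astype("datetime64[D]")
        return pd.Series(out.astype("datetime64[ns]"), index=s.index)

    patients = pd.DataFrame(rows["patients"], columns=list(_SCHEMA["patients"]))
    for c in ("birth_date", "death_date", "registration_start", "registration_end",
              "up_to_standard_date", "last_collection_date"):
        patients[c] = days_to_ts(patients[c])
    events = pd.DataFrame(rows["events"], columns=list(_SCHEMA["events"]))
    events["event_date"] = days_to_ts(events["event_date"])
    rx = pd.DataFrame(rows["prescriptions"], columns=list(_SCHEMA["prescriptions"]))
    rx["issue_date"] = days_to_ts(rx["issue_date"])
    spells = pd.DataFrame(rows["spells"], columns=list(_SCHEMA["spells"]))
    spells["admission_date"] = days_to_ts(spells["admission_date"])
    spells["discharge_date"] = days_to_ts(spells["discharge_date"])
    ae = pd.DataFrame(rows["ae"], columns=list(_SCHEMA["ae"]))
    ae["attendance_date"] = days_to_ts(ae["attendance_date"])
    deaths = pd.DataFrame(rows["deaths"], columns=list(_SCHEMA["deaths"]))
    deaths["death_date"] = days_to_ts(deaths["death_date"])

    truth = pd.DataFrame(
        rows["truth"],
        columns=["patient_id", "onset_day", "not_immediate", "bsi",
                 "home_visit", "prior_abx_30d", "female", "age_per5_c", "cci"]
    )
    if len(truth):
        truth["onset_date"] = days_to_ts(truth["onset_day"])

    return TableBundle(
        patients=_coerce(patients, "patients"),
        events=_coerce(events, "events"),
        prescriptions=_coerce(rx, "prescriptions"),
        spells=_coerce(spells, "spells"),
        ae=_coerce(ae, "ae"),
        deaths=_coerce(deaths, "deaths"),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# I/O


def emit_tables(bundle: TableBundle, directory: str | Path) -> dict[str, Path]:
    """Write one CSV per table (plus the codelist) into ``directory``.

    Files round-trip losslessly through :func:`read_tables`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, df in bundle.tables().items():
        path = directory / f"{name}.csv"
        try:
            df.to_csv(path, index=False, date_format="%Y-%m-%d")
        except OSError as exc:  # pragma: no cover - environment dependent
            raise OSError(f"failed writing table file {path}: {exc}") from exc
        written[name] = path
    from uti_episodes.codelist import load_codelist

    load_codelist().to_csv(directory / "codelist.csv", index=False)
    written["codelist"] = directory / "codelist.csv"
    return written


def read_tables(directory: str | Path) -> TableBundle:
    """Read a bundle previously written by :func:`emit_tables`."""
    directory = Path(directory)
    frames = {}
    for name, schema in _SCHEMA.items():
        path = directory / f"{name}.csv"
        if not path.exists():
            raise FileNotFoundError(f"missing table file {path}")
        df = pd.read_csv(path, dtype=object)
        frames[name] = _coerce(df, name)
    return TableBundle(**frames)
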