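"""Cluster-robust marginal logistic models and the NNEH.

Associations between not-immediate antibiotic prescribing and 60-day
outcomes are estimated with generalized estimating equations (GEE): logit
link, exchangeable working correlation to absorb repeated UTI episodes per
patient, and Huber-White sandwich standard errors for all confidence
intervals (Wald, 1.96 multiplier).  The final multivariable model keeps the
exposure and every covariate passing a univariable p < 0.2 screen (joint
robust Wald test for multi-level categoricals).  The number needed to be
exposed to harm (NNEH) is the reciprocal of the covariate-standardised
average risk difference between exposure levels, with percentile confidence
intervals from a cluster (patient-level) bootstrap.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.genmod.cov_struct import Exchangeable, Independence
from statsmodels.genmod.families import Binomial

from uti_episodes.derivations import (
    CANDIDATE_COVARIATES,
    CATEGORICAL_COVARIATES,
    build_analysis_rows,
)

Z95 = 1.959963984540054
GEE_MAXITER = 100
GEE_CTOL = 1e-8

EXPOSURE = "not_immediate"


@dataclass(frozen=True)
class TermEstimate:
    name: str
    estimate: float       # log-odds scale
    robust_se: float
    ci_low: float
    ci_high: float
    p_value: float

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.estimate)


@dataclass
class FitResult:
    outcome: str
    terms: list[TermEstimate]
    correlation_structure: str
    n_obs: int
    n_clusters: int
    converged: bool
    formula: str = ""
    selected_terms: list[str] = field(default_factory=list)
    model_result: object = field(default=None, repr=False)

    def term(self, name: str) -> TermEstimate:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(f"no term {name!r} in fit (have {[t.name for t in self.terms]})")

    def exposure_or(self) -> float:
        return self.term(EXPOSURE).odds_ratio

    def or_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": [t.name for t in self.terms],
                "OR": [math.exp(t.estimate) for t in self.terms],
                "ci_low": [math.exp(t.ci_low) for t in self.terms],
                "ci_high": [math.exp(t.ci_high) for t in self.terms],
                "p": [t.p_value for t in self.terms],
            }
        )


def _term_expr(name: str) -> str:
    return f"C({name})" if name in CATEGORICAL_COVARIATES else name

def build_formula(outcome: str, terms: list[str]) -> str:
    rhs = " + ".join(_term_expr(t) for t in terms) if terms else "1"
    return f"{outcome} ~ {rhs}"


def _prepare(rows: pd.DataFrame, terms: list[str]) -> pd.DataFrame:
    df = rows.copy()
    for t in terms:
        base = t.split(":")[0]
        if base in df.columns and isinstance(df[base].dtype, pd.CategoricalDtype):
            df[base] = df[base].cat.remove_unused_categories()
    return df


def fit_gee_logit(
    rows: pd.DataFrame,
    outcome: str,
    terms: list[str],
    cluster: str = "patient_id",
    cov_struct: str = "exchangeable",
    weights: np.ndarray | None = None,
    maxiter: int = GEE_MAXITER,
    ctol: float = GEE_CTOL,
) -> FitResult:
    """Marginal logistic regression with cluster-robust (sandwich) CIs.

    ``terms`` are column names (categoricals expand to reference-coded
    indicators) or explicit patsy expressions such as interaction products.
    On non-convergence the model is refitted under an independence working
    correlation and flagged.
    """
    if rows[cluster].nunique() < 2:
        raise ValueError("GEE requires at least 2 clusters")
    df = _prepare(rows, terms)
    formula = build_formula(outcome, terms)

    def _fit(struct):
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            model = sm.GEE.from_formula(
                formula, groups=cluster, data=df, family=Binomial(),
                cov_struct=struct, weights=weights,
            )
            res = model.fit(maxiter=maxiter, ctol=ctol)
        failed = any("convergence" in str(w.message).lower() for w in caught)
        failed = failed or not np.all(np.isfinite(res.params))
        return res, not failed

    res, converged = _fit(Exchangeable() if cov_struct == "exchangeable" else Independence())
    label = cov_struct
    if not converged and cov_struct == "exchangeable":
        res, _ = _fit(Independence())
        label = "independence (fallback after exchangeable non-convergence)"

    est = res.params
    se = res.bse  # robust (sandwich) by default
    terms_out = [
        TermEstimate(
            name=nm,
            estimate=float(est[nm]),
            robust_se=float(se[nm]),
            ci_low=float(est[nm] - Z95 * se[nm]),
            ci_high=float(est[nm] + Z95 * se[nm]),
            p_value=float(res.pvalues[nm]),
        )
        for nm in est.index
    ]
    return FitResult(
        outcome=outcome,
        terms=terms_out,
        correlation_structure=label,
        n_obs=int(res.nobs),
        n_clusters=int(df[cluster].nunique()),
        converged=bool(converged),
        formula=formula,
        model_result=res,
    )


def joint_wald_pvalue(fit: FitResult, variable: str) -> float:
    """Robust Wald p-value across all indicator columns of one variable."""
    res = fit.model_result
    names = list(res.params.index)
    prefix = f"C({variable})["
    cols = [i for i, nm in enumerate(names) if nm.startswith(prefix) or nm == variable]
    if not cols:
        raise KeyError(f"variable {variable!r} not in model")
    r = np.zeros((len(cols), len(names)))
    for j, i in enumerate(cols):
        r[j, i] = 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        wt = res.wald_test(r, scalar=True)
    return float(wt.pvalue)


def _estimable(rows: pd.DataFrame, var: str, outcome: str) -> bool:
    """True when every level of a discrete covariate holds both outcome
    classes (a zero cell implies a divergent maximum-likelihood estimate)."""
    tab = pd.crosstab(rows[var], rows[outcome], dropna=True)
    tab = tab.loc[tab.sum(axis=1) > 0]  # ignore unused categorical levels
    if tab.shape[1] < 2:
        return False
    return bool((tab.to_numpy() > 0).all())


def screen_univariable(
    rows: pd.DataFrame,
    candidates: list[str] | None = None,
    outcome: str = "bsi_60",
    alpha: float = 0.2,
    cluster: str = "patient_id",
    return_pvalues: bool = False,
):
    """Select covariates with univariable GEE p < ``alpha``.

    Multi-level categoricals are judged by the joint robust Wald test across
    their indicators.  Degenerate candidates (constant, or failing to fit)
    are never selected.
    """
    if candidates is None:
        candidates = CANDIDATE_COVARIATES
    pvals: dict[str, float] = {}
    for var in candidates:
        col = rows[var]
        nuniq = col.nunique(dropna=True)
        if nuniq < 2:
            pvals[var] = math.nan
            continue
        if nuniq <= 12 and not _estimable(rows, var, outcome):
            # a level with no events (or no non-events) is inestimable by
            # maximum likelihood and would push the GEE to divergence
            pvals[var] = math.nan
            continue
        try:
            # lighter convergence settings: univariable p-values are stable
            # to ~1e-12 well before the final-model tolerance
            f = fit_gee_logit(rows, outcome, [var], cluster=cluster,
                              maxiter=30, ctol=1e-6)
            if var in CATEGORICAL_COVARIATES and nuniq > 2:
                pvals[var] = joint_wald_pvalue(f, var)
            else:
                nm = next(t.name for t in f.terms if t.name != "Intercept")
                pvals[var] = f.term(nm).p_value
        except Exception:
            pvals[var] = math.nan
    selected = [v for v in candidates if pvals.get(v, math.nan) == pvals.get(v) and pvals[v] < alpha]
    return (selected, pvals) if return_pvalues else selected


def fit_final_model(
    rows: pd.DataFrame,
    outcome: str = "bsi_60",
    candidates: list[str] | None = None,
    alpha: float = 0.2,
    cluster: str = "patient_id",
) -> FitResult:
    """Univariable screen then multivariable GEE; exposure always retained."""
    selected = screen_univariable(rows, candidates, outcome, alpha, cluster)
    selected = [v for v in selected if rows[v].nunique(dropna=True) > 1]
    fit = fit_gee_logit(rows, outcome, [EXPOSURE] + selected, cluster=cluster)
    fit.selected_terms = selected
    return fit


def fit_interactions(
    rows: pd.DataFrame,
    modifier: str,
    outcome: str = "bsi_60",
    base_terms: list[str] | None = None,
    cluster: str = "patient_id",
) -> tuple[FitResult, dict[str, FitResult]]:
    """Exposure-by-modifier product term plus per-stratum exposure fits.

    ``modifier`` is ``gender`` (product with the female indicator; strata
    female/male) or ``age`` (product with continuous age per 5 years; strata
    65-79 / 80+).
    """
    if modifier not in ("gender", "age"):
        raise ValueError("modifier must be 'gender' or 'age'")
    mod_col = "female" if modifier == "gender" else "age_per5"
    if rows[mod_col].nunique() < 2:
        raise ValueError(f"degenerate interaction: modifier {mod_col!r} is constant")
    base_terms = list(base_terms or [])
    terms = [EXPOSURE] + ([mod_col] if mod_col not in base_terms else []) + base_terms \
        + [f"{EXPOSURE}:{mod_col}"]
    inter = fit_gee_logit(rows, outcome, terms, cluster=cluster)

    strata: dict[str, FitResult] = {}
    if modifier == "gender":
        groups = {"female": rows["female"] == 1, "male": rows["female"] == 0}
    else:
        groups = {"65-79": rows["age_years"] < 80, "80+": rows["age_years"] >= 80}
    sub_terms = [EXPOSURE] + [t for t in base_terms if t != mod_col]
    for label, mask in groups.items():
        sub = rows.loc[mask]
        if sub[EXPOSURE].nunique() > 1 and sub[outcome].nunique() > 1 and sub[cluster].nunique() >= 2:
            keep = [t for t in sub_terms if t == EXPOSURE or sub[t].nunique(dropna=True) > 1]
            strata[label] = fit_gee_logit(sub, outcome, keep, cluster=cluster)
    return inter, strata


# ---------------------------------------------------------------------------
# NNEH


@dataclass
class NNEHResult:
    ard: float                      # average risk difference (not-immediate minus immediate)
    nneh_point: float               # 1 / ard; +/-inf when ard == 0
    ard_ci: tuple[float, float]
    boot_ci: tuple[float, float]    # NNEH scale
    n_boot: int
    resample_unit: str = "patient"
    infinite: bool = False


def _ard_from_result(res, rows: pd.DataFrame) -> float:
    hi = rows.copy()
    hi[EXPOSURE] = 1
    lo = rows.copy()
    lo[EXPOSURE] = 0
    return float(np.mean(res.predict(hi) - res.predict(lo)))


def average_risk_difference_nneh(
    fit: FitResult,
    rows: pd.DataFrame,
    n_boot: int = 200,
    seed: int = 0,
    cluster: str = "patient_id",
) -> NNEHResult:
    """Standardised average risk difference and NNEH with cluster bootstrap.

    Every row's outcome risk is predicted under both exposure levels with
    covariates held fixed (marginal standardisation over the observed
    covariate distribution of all rows); patients are resampled with
    replacement and the final model refitted in each of ``n_boot`` samples.
    """
    if not fit.converged:
        raise ValueError("refusing to standardise over a non-converged fit")
    df = _prepare(rows, [t.name for t in fit.terms])
    ard = _ard_from_result(fit.model_result, df)
    if ard == 0.0:
        return NNEHResult(0.0, math.inf, (0.0, 0.0), (math.inf, math.inf),
                          n_boot=0, infinite=True)
    nneh = 1.0 / ard

    rng = np.random.default_rng(seed)
    gb = df.groupby(cluster, sort=False).indices
    ids = np.array(list(gb.keys()))
    boots = []
    for _ in range(n_boot):
        pick = rng.integers(0, len(ids), size=len(ids))
        idx = np.concatenate([gb[ids[i]] for i in pick])
        bs = df.iloc[idx].copy()
        bs["_boot_cluster"] = np.repeat(
            np.arange(len(pick)), [len(gb[ids[i]]) for i in pick]
        )
        for col in bs.columns:  # resampling can drop category levels
            if isinstance(bs[col].dtype, pd.CategoricalDtype):
                bs[col] = bs[col].cat.remove_unused_categories()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.GEE.from_formula(
                    fit.formula, groups="_boot_cluster", data=bs,
                    family=Binomial(), cov_struct=Exchangeable(),
                )
                res = model.fit(maxiter=GEE_MAXITER, ctol=GEE_CTOL)
            boots.append(_ard_from_result(res, bs))
        except Exception:
            continue
    if boots:
        lo, hi = np.percentile(boots, [2.5, 97.5])
    else:  # pragma: no cover - pathological
        lo = hi = math.nan
    # NNEH bounds: reciprocal of the ARD interval; unbounded when it spans 0
    if lo > 0 and hi > 0:
        nneh_ci = (1.0 / hi, 1.0 / lo)
    elif lo < 0 and hi < 0:
        nneh_ci = (1.0 / hi, 1.0 / lo)
    else:
        nneh_ci = (1.0 / hi if hi != 0 else math.inf, math.inf)
    return NNEHResult(
        ard=ard, nneh_point=nneh, ard_ci=(float(lo), float(hi)),
        boot_ci=(float(nneh_ci[0]), float(nneh_ci[1])), n_boot=len(boots),
    )


# ---------------------------------------------------------------------------
# Sensitivity variants


def run_sensitivity(
    bundle,
    study_start,
    study_end,
    variant: str,
    outcome: str = "bsi_60",
    candidates: list[str] | None = None,
) -> FitResult:
    """Re-run the pipeline under a sensitivity variant and fit the final model.

    ``window30`` repeats episode segmentation and all outcome/wash-out
    windows at 30 days; ``first_episode_only`` keeps each patient's first
    analyzed episode.
    """
    if variant == "window30":
        rows = build_analysis_rows(bundle, study_start, study_end, window_days=30)
    elif variant == "first_episode_only":
        rows = build_analysis_rows(bundle, study_start, study_end, window_days=60)
        rows = (
            rows.sort_values(["patient_id", "start_date"])
            .groupby("patient_id", as_index=False, observed=True)
            .head(1)
            .reset_index(drop=True)
        )
    else:
        raise ValueError("variant must be 'window30' or 'first_episode_only'")
    return fit_final_model(rows, outcome=outcome, candidates=candidates)
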