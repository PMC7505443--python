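"""Propensity-score sensitivity analyses for confounding by indication.

The probability of *not* receiving an immediate antibiotic is estimated two
ways — parametric multivariable logistic regression and nonparametric
gradient-boosted trees (shallow trees, small shrinkage, iteration count
chosen by a covariate-balance criterion) — and each score is used two ways:
greedy nearest-neighbour matching of every exposed episode to up to five
controls within a caliper of 0.2 SD of the logit score, and stabilised
inverse-probability-of-treatment weighting targeting the average treatment
effect (ATE).  Matched sets feed either the cluster-robust marginal model
of the main analysis or a conditional logistic regression stratified on the
matched set.  Balance is reported as standardised mean differences (SMD)
before and after adjustment.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from patsy import dmatrix
from sklearn.ensemble import GradientBoostingClassifier
from statsmodels.discrete.conditional_models import ConditionalLogit

from uti_episodes.derivations import CANDIDATE_COVARIATES
from uti_episodes.estimation import EXPOSURE, Z95, fit_gee_logit, _term_expr

DEFAULT_CALIPER_SD = 0.2
DEFAULT_K = 5
_BOOST_PARAMS = dict(max_depth=2, learning_rate=0.01, n_estimators=800, subsample=0.8)
_BOOST_EVAL_STRIDE = 25


@dataclass
class PropensityResult:
    ps_method: str                    # logistic | boosted_trees
    adjustment: str                   # match_le5 | ipw
    analysis_model: str               # cluster_robust_marginal | conditional_matched
    estimand: str
    or_estimate: float
    ci: tuple[float, float]
    p_value: float
    n_obs: int
    n_matched_sets: int | None = None
    n_unmatched_exposed: int | None = None
    effective_sample_size: float | None = None
    n_weights_truncated: int | None = None
    balance: pd.DataFrame | None = field(default=None, repr=False)
    metadata: dict = field(default_factory=dict)


def _design(rows: pd.DataFrame, covariates: list[str], intercept: bool = False) -> pd.DataFrame:
    """Expanded covariate matrix.

    Without an intercept every categorical level gets its own indicator
    (the form used for balance reporting); with one, categoricals are
    reference-coded so the matrix is full rank for model fitting.
    """
    df = rows.copy()
    for c in covariates:
        if isinstance(df[c].dtype, pd.CategoricalDtype):
            df[c] = df[c].cat.remove_unused_categories()
    rhs = " + ".join(_term_expr(c) for c in covariates)
    lead = "1 + " if intercept else "0 + "
    return dmatrix(lead + rhs, df, return_type="dataframe")


def standardized_mean_differences(
    x: pd.DataFrame, treated: np.ndarray, weights: np.ndarray | None = None
) -> pd.Series:
    """Absolute SMD per design column, optionally under weights.

    Pooled SD is computed from the unweighted groups so that before/after
    comparisons share a denominator.
    """
    treated = np.asarray(treated, dtype=bool)
    w = np.ones(len(x)) if weights is None else np.asarray(weights, dtype=float)
    out = {}
    for col in x.columns:
        v = x[col].to_numpy(dtype=float)
        sd = math.sqrt((v[treated].var(ddof=1) + v[~treated].var(ddof=1)) / 2.0)
        if sd == 0:
            out[col] = 0.0
            continue
        mt = np.average(v[treated], weights=w[treated])
        mc = np.average(v[~treated], weights=w[~treated])
        out[col] = abs(mt - mc) / sd
    return pd.Series(out, name="smd")


def estimate_propensity(
    rows: pd.DataFrame,
    method: str = "logistic",
    covariates: list[str] | None = None,
    seed: int = 0,
    return_info: bool = False,
):
    """Per-row probability of not-immediate prescribing.

    ``logistic`` fits a multivariable logistic regression on the same
    covariate set as the outcome model's candidates; ``boosted_trees`` fits
    a gradient-boosted classifier and picks the boosting iteration that
    minimises the mean absolute SMD under the implied IPT weights.
    """
    covariates = covariates or CANDIDATE_COVARIATES
    x = _design(rows, covariates)
    y = rows[EXPOSURE].to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError("exposure has a single level; propensity model is undefined")

    if method == "logistic":
        xm = _design(rows, covariates, intercept=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                # IRLS with a pseudo-inverse tolerates collinear columns
                res = sm.GLM(y, xm, family=sm.families.Binomial()).fit(maxiter=200)
            except Exception as exc:
                raise ValueError(
                    "propensity model failed (possible perfect separation); "
                    "consider a scenario with overlapping covariate support"
                ) from exc
        scores = np.asarray(res.predict(xm))
        if not np.all(np.isfinite(res.params)) or np.abs(res.params).max() > 30:
            raise ValueError(
                "perfect separation in the propensity model; "
                "consider a scenario with overlapping covariate support"
            )
        info = {"model": res, "method": "logistic"}
    elif method == "boosted_trees":
        clf = GradientBoostingClassifier(random_state=seed, **_BOOST_PARAMS)
        clf.fit(x.to_numpy(), y)
        p_marg = y.mean()
        best = (math.inf, None, None)
        for i, proba in enumerate(clf.staged_predict_proba(x.to_numpy())):
            it = i + 1
            if it % _BOOST_EVAL_STRIDE and it != clf.n_estimators_:
                continue
            s = np.clip(proba[:, 1], 1e-6, 1 - 1e-6)
            w = np.where(y == 1, p_marg / s, (1 - p_marg) / (1 - s))
            crit = standardized_mean_differences(x, y == 1, w).mean()
            if crit < best[0]:
                best = (crit, it, s)
        scores = best[2]
        info = {"method": "boosted_trees", "n_iterations": best[1],
                "balance_criterion": float(best[0])}
    else:
        raise ValueError("method must be 'logistic' or 'boosted_trees'")

    scores = np.clip(scores, 1e-6, 1 - 1e-6)
    return (scores, info) if return_info else scores


def match_up_to_k(
    rows: pd.DataFrame,
    scores: np.ndarray,
    k: int = DEFAULT_K,
    caliper_sd: float = DEFAULT_CALIPER_SD,
) -> pd.DataFrame:
    """Greedy nearest-neighbour matching without replacement on the logit score.

    Exposed (not-immediate) rows are processed in descending score order;
    each receives up to ``k`` nearest-score controls within a caliper of
    ``caliper_sd`` standard deviations of the logit score.  Returns a frame
    indexed like ``rows`` with columns ``ps_set`` (nullable set id) and
    ``ps_role``; unmatched exposed rows keep a null set id.
    """
    scores = np.asarray(scores, dtype=float)
    logit = np.log(scores / (1 - scores))
    caliper = caliper_sd * logit.std(ddof=1)
    treated = rows[EXPOSURE].to_numpy() == 1

    ctrl_pos = np.flatnonzero(~treated)
    order = np.argsort(logit[ctrl_pos], kind="stable")
    ctrl_sorted = ctrl_pos[order]
    ctrl_logit = logit[ctrl_sorted]
    available = np.ones(len(ctrl_sorted), dtype=bool)

    set_id = np.full(len(rows), -1, dtype=np.int64)
    exp_pos = np.flatnonzero(treated)
    exp_order = exp_pos[np.argsort(-logit[exp_pos], kind="stable")]

    n_sets = 0
    n_unmatched = 0
    for pos in exp_order:
        target = logit[pos]
        j = np.searchsorted(ctrl_logit, target)
        picks: list[int] = []
        left, right = j - 1, j
        while len(picks) < k:
            dl = target - ctrl_logit[left] if left >= 0 else math.inf
            dr = ctrl_logit[right] - target if right < len(ctrl_logit) else math.inf
            if dl > caliper and dr > caliper:
                break
            if dr <= dl:
                if available[right] and dr <= caliper:
                    picks.append(right)
                right += 1
            else:
                if available[left] and dl <= caliper:
                    picks.append(left)
                left -= 1
        if picks:
            sid = n_sets
            n_sets += 1
            set_id[pos] = sid
            for p in picks:
                available[p] = False
                set_id[ctrl_sorted[p]] = sid
        else:
            n_unmatched += 1

    if n_sets == 0:
        raise ValueError(
            f"no matches formed: caliper {caliper:.4f} on the logit score "
            f"(SD {logit.std(ddof=1):.4f}, {treated.sum()} exposed, "
            f"{(~treated).sum()} controls)"
        )
    out = pd.DataFrame(index=rows.index)
    out["ps_set"] = pd.array([s if s >= 0 else None for s in set_id], dtype="Int64")
    role = np.where(treated, "exposed", "control")
    out["ps_role"] = np.where(set_id >= 0, role, "unmatched")
    out.attrs["n_sets"] = n_sets
    out.attrs["n_unmatched_exposed"] = n_unmatched
    out.attrs["caliper"] = float(caliper)
    return out


def matched_weights(set_ids, treated) -> np.ndarray:
    """Variable-ratio matching weights: exposed 1, controls 1/(set size)."""
    set_ids = np.asarray(set_ids)
    treated = np.asarray(treated, dtype=bool)
    w = np.ones(len(set_ids), dtype=float)
    ctrl = ~treated
    sizes = pd.Series(set_ids[ctrl]).value_counts()
    w[ctrl] = 1.0 / sizes.loc[set_ids[ctrl]].to_numpy()
    return w


def ipw_weights(
    rows: pd.DataFrame,
    scores: np.ndarray,
    truncate: tuple[float, float] = (0.01, 0.99),
) -> tuple[np.ndarray, int]:
    """Stabilised ATE weights, truncated at the 1st/99th weight percentiles.

    Returns ``(weights, n_truncated)``.
    """
    scores = np.asarray(scores, dtype=float)
    treated = rows[EXPOSURE].to_numpy() == 1
    p = treated.mean()
    w = np.where(treated, p / scores, (1 - p) / (1 - scores))
    lo, hi = np.quantile(w, truncate)
    clipped = np.clip(w, lo, hi)
    return clipped, int(np.sum(clipped != w))


def adjust_with_propensity(
    rows: pd.DataFrame,
    ps_method: str = "logistic",
    adjustment: str = "match_le5",
    analysis_model: str = "cluster_robust_marginal",
    outcome: str = "bsi_60",
    k: int = DEFAULT_K,
    caliper_sd: float = DEFAULT_CALIPER_SD,
    covariates: list[str] | None = None,
    seed: int = 0,
    scores: np.ndarray | None = None,
) -> PropensityResult:
    """One cell of the 2x2 propensity-score design (method x adjustment).

    Matching feeds either the marginal GEE of the main analysis or a
    conditional logistic regression stratified on matched set; weighting
    feeds a weighted independence-GEE with robust SEs.  Precomputed
    ``scores`` (from :func:`estimate_propensity`) may be passed to avoid
    refitting the score model.
    """
    covariates = covariates or CANDIDATE_COVARIATES
    if scores is None:
        scores = estimate_propensity(rows, method="logistic" if ps_method == "logistic" else "boosted_trees",
                                     covariates=covariates, seed=seed)
    x = _design(rows, covariates)
    treated = rows[EXPOSURE].to_numpy() == 1
    smd_before = standardized_mean_differences(x, treated)

    meta = {"caliper_sd": caliper_sd, "k": k, "matching": "greedy, without replacement"}
    n_sets = n_unmatched = None
    ess = n_trunc = None

    if adjustment == "match_le5":
        m = match_up_to_k(rows, scores, k=k, caliper_sd=caliper_sd)
        keep = m["ps_set"].notna().to_numpy()
        sub = rows.loc[keep].copy()
        sub["ps_set"] = m.loc[keep, "ps_set"].astype(int).to_numpy()
        smd_after = standardized_mean_differences(
            x.loc[keep], treated[keep], matched_weights(sub["ps_set"], treated[keep])
        )
        n_sets = m.attrs["n_sets"]
        n_unmatched = m.attrs["n_unmatched_exposed"]
        meta["caliper"] = m.attrs["caliper"]
        if analysis_model == "conditional_matched":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = ConditionalLogit(
                    sub[outcome].to_numpy(), sub[[EXPOSURE]].to_numpy(),
                    groups=sub["ps_set"].to_numpy(),
                ).fit(disp=0)
            b, se = float(res.params[0]), float(res.bse[0])
            est, ci, p = math.exp(b), (math.exp(b - Z95 * se), math.exp(b + Z95 * se)), float(res.pvalues[0])
            n_obs = int(len(sub))
        else:
            f = fit_gee_logit(sub, outcome, [EXPOSURE])
            t = f.term(EXPOSURE)
            est, ci, p = t.odds_ratio, (math.exp(t.ci_low), math.exp(t.ci_high)), t.p_value
            n_obs = f.n_obs
    elif adjustment == "ipw":
        w, n_trunc = ipw_weights(rows, scores)
        smd_after = standardized_mean_differences(x, treated, w)
        ess = float(w.sum() ** 2 / np.sum(w ** 2))
        f = fit_gee_logit(rows, outcome, [EXPOSURE], cov_struct="independence", weights=w)
        t = f.term(EXPOSURE)
        est, ci, p = t.odds_ratio, (math.exp(t.ci_low), math.exp(t.ci_high)), t.p_value
        n_obs = f.n_obs
        analysis_model = "cluster_robust_marginal"
    else:
        raise ValueError("adjustment must be 'match_le5' or 'ipw'")

    balance = pd.DataFrame({"smd_before": smd_before, "smd_after": smd_after})
    return PropensityResult(
        ps_method=ps_method,
        adjustment=adjustment,
        analysis_model=analysis_model,
        estimand="ATE" if adjustment == "ipw" else "ATT (matched sets)",
        or_estimate=est,
        ci=ci,
        p_value=p,
        n_obs=n_obs,
        n_matched_sets=n_sets,
        n_unmatched_exposed=n_unmatched,
        effective_sample_size=ess,
        n_weights_truncated=n_trunc,
        balance=balance,
        metadata=meta,
    )


def propensity_grid(
    rows: pd.DataFrame,
    outcome: str = "bsi_60",
    covariates: list[str] | None = None,
    seed: int = 0,
) -> list[PropensityResult]:
    """The four adjusted analyses: {logistic, boosted} x {matching, IPW}."""
    out = []
    for method in ("logistic", "boosted_trees"):
        scores = estimate_propensity(rows, method=method, covariates=covariates, seed=seed)
        for adj in ("match_le5", "ipw"):
            out.append(
                adjust_with_propensity(
                    rows, ps_method=method, adjustment=adj, outcome=outcome,
                    covariates=covariates, seed=seed, scores=scores,
                )
            )
    return out
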