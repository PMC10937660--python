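"""Single-exposure disease-risk models.

Covariate-adjusted binary logistic regression (disease outcomes) and
multiple linear regression (continuous clinical parameters) on log10
exposure; odds ratios are per one-unit increase of log10(ng/mL).  The
stratified variant re-matches and refits within age bins [30,50),
[50,60), [60,80] and within sex strata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .config import EPI_FACTORS
from .design import build_covariate_design, drop_collinear, standardize
from .outcomes import match_controls

log = logging.getLogger(__name__)

AGE_BINS = ((30, 50), (50, 60), (60, 80))


@dataclass
class AssociationResult:
    chemical: str
    outcome: str
    model: str                      # "logistic" | "linear"
    beta: float = np.nan            # per log10(ng/mL)
    se: float = np.nan
    or_: float = np.nan             # exp(beta), logistic only
    ci_low: float = np.nan
    ci_high: float = np.nan
    p: float = np.nan
    n_cases: int = 0
    n_controls: int = 0
    covariates: tuple = ()
    stratum: str = "all"
    converged: bool = True
    hosmer_lemeshow_p: float = np.nan
    low_frequency: bool = False
    extra: dict = field(default_factory=dict)


def hosmer_lemeshow(y: np.ndarray, p: np.ndarray, g: int = 10) -> float:
    """Hosmer-Lemeshow goodness-of-fit p value (decile-of-risk groups)."""
    from scipy.stats import chi2

    order = np.argsort(p, kind="stable")
    y, p = np.asarray(y, float)[order], np.asarray(p, float)[order]
    groups = np.array_split(np.arange(len(y)), g)
    stat = 0.0
    used = 0
    for idx in groups:
        if len(idx) == 0:
            continue
        o, e = y[idx].sum(), p[idx].sum()
        n = len(idx)
        denom = e * (1 - e / n)
        if denom <= 0:
            continue
        stat += (o - e) ** 2 / denom
        used += 1
    if used <= 2:
        return np.nan
    return float(chi2.sf(stat, used - 2))


def _design(cohort: pd.DataFrame, exposure_log10: pd.Series, covariates):
    Z = standardize(build_covariate_design(cohort, covariates))
    X = pd.concat([exposure_log10.rename("log10_exposure"), Z], axis=1)
    return sm.add_constant(drop_collinear(X).astype(float))


def fit_single_exposure(exposure: pd.Series, outcome: pd.Series,
                        cohort: pd.DataFrame, *, chemical: str = "",
                        outcome_name: str = "", covariates=EPI_FACTORS,
                        model: str = "logistic", log_transform: bool = True,
                        wald: bool = True) -> AssociationResult:
    """Fit one chemical against one outcome / clinical parameter.

    ``exposure`` is the (imputed, positive) concentration; it is log10
    transformed here unless already transformed.  All series must share
    the cohort's index.  Perfect separation or non-convergence yields a
    flagged, NaN-valued result rather than a number.
    """
    keep = exposure.notna() & outcome.notna()
    exposure, outcome, coh = exposure[keep], outcome[keep], cohort.loc[keep]
    if exposure.empty:
        raise ValueError("no complete observations")
    x = np.log10(exposure.astype(float)) if log_transform else exposure.astype(float)
    if x.nunique() <= 1:
        raise ValueError("zero exposure variance")
    X = _design(coh, x, covariates)
    result = AssociationResult(chemical=chemical, outcome=outcome_name, model=model,
                               covariates=tuple(covariates))
    if model == "logistic":
        y = outcome.astype(float)
        result.n_cases = int(y.sum())
        result.n_controls = int((1 - y).sum())
        try:
            with np.errstate(all="ignore"):
                res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
            se_x = res.bse["log10_exposure"]
            # huge se signals (quasi-)separation: no finite ML estimate
            if not res.converged or not np.isfinite(se_x) or se_x > 1e3:
                raise RuntimeError("non-convergence or separation")
        except Exception as exc:
            log.warning("logistic fit failed (%s/%s): %s", chemical, outcome_name, exc)
            result.converged = False
            return result
        beta = float(res.params["log10_exposure"])
        se = float(res.bse["log10_exposure"])
        result.beta, result.se = beta, se
        result.or_ = float(np.exp(beta))
        if wald:
            result.ci_low = float(np.exp(beta - 1.96 * se))
            result.ci_high = float(np.exp(beta + 1.96 * se))
        else:
            lo, hi = res.conf_int().loc["log10_exposure"]
            result.ci_low, result.ci_high = float(np.exp(lo)), float(np.exp(hi))
        result.p = float(res.pvalues["log10_exposure"])
        result.hosmer_lemeshow_p = hosmer_lemeshow(y.to_numpy(), res.predict(X))
    elif model == "linear":
        res = sm.OLS(outcome.astype(float), X).fit()
        result.beta = float(res.params["log10_exposure"])
        result.se = float(res.bse["log10_exposure"])
        result.ci_low, result.ci_high = (
            float(v) for v in res.conf_int().loc["log10_exposure"])
        result.p = float(res.pvalues["log10_exposure"])
        result.n_cases = len(outcome)
    else:
        raise ValueError(f"unknown model {model!r}")
    return result


def fit_matched(matched, matrix_values: pd.DataFrame, cohort: pd.DataFrame,
                labels: pd.DataFrame, chemical: str, *, covariates=EPI_FACTORS,
                stratum: str = "all") -> AssociationResult:
    """Logistic fit on a matched case-control set."""
    ids = list(matched.case_ids) + list(matched.control_ids)
    coh = cohort.set_index("subject_id") if "subject_id" in cohort else cohort
    lab = labels.set_index("subject_id") if "subject_id" in labels else labels
    exp_s = matrix_values[chemical].reindex(ids)
    y = (lab[matched.outcome].reindex(ids) == True).astype(float)  # noqa: E712
    res = fit_single_exposure(exp_s, y, coh.loc[ids], chemical=chemical,
                              outcome_name=matched.outcome,
                              covariates=covariates, model="logistic")
    res.stratum = stratum
    return res


def age_stratum(age: float) -> str | None:
    """Half-open bins [30,50), [50,60), closed at 80: age 50 -> "50-60"."""
    for lo, hi in AGE_BINS:
        if (lo <= age < hi) or (hi == AGE_BINS[-1][1] and lo <= age <= hi):
            return f"{lo}-{hi}"
    return None


def stratified_risk(matrix_values: pd.DataFrame, cohort: pd.DataFrame,
                    labels: pd.DataFrame, outcome: str, chemical: str,
                    strata: str = "age", *, covariates=EPI_FACTORS) -> list:
    """Re-match and refit within each age bin or sex stratum."""
    coh = cohort.set_index("subject_id") if "subject_id" in cohort else cohort
    lab = labels.set_index("subject_id") if "subject_id" in labels else labels
    if strata == "age":
        groups = coh["age"].map(age_stratum)
    elif strata == "sex":
        groups = coh["sex"]
    else:
        raise ValueError("strata must be 'age' or 'sex'")
    out = []
    strat_covs = [c for c in covariates if c not in
                  (("age",) if strata == "age" else ("sex",))]
    for g in sorted(groups.dropna().unique()):
        ids = groups.index[groups == g]
        try:
            m = match_controls(coh.loc[ids].reset_index(),
                               lab.loc[ids].reset_index(), outcome,
                               covariates=strat_covs)
            r = fit_matched(m, matrix_values, coh.reset_index(),
                            lab.reset_index(), chemical,
                            covariates=strat_covs, stratum=str(g))
            out.append(r)
        except ValueError as exc:
            log.warning("stratum %s skipped: %s", g, exc)
    return out


def results_frame(results) -> pd.DataFrame:
    rows = []
    for r in results:
        d = vars(r).copy()
        d.pop("extra", None)
        d["covariates"] = ";".join(d["covariates"])
        rows.append(d)
    return pd.DataFrame(rows)
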