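"""Chronic-disease outcome classification and propensity matching.

Twelve outcome labels are derived from the nine clinical parameters:
nine single-parameter rules (diagnostic thresholds, all >= except
obesity's strict >), plus three composites - hypertension (high SBP or
high DBP), hyperlipidemia (any of high LDL-C / hypertriglyceridemia /
hypercholesterolemia) and metabolic syndrome (>= 3 of abdominal obesity,
hypertriglyceridemia, hypertension, diabetes).  Missing parameters
propagate as missing labels (Kleene logic), never as false.

Case-control sets per outcome come from propensity-score matching:
a logistic model of case status on the nine epidemiological factors plus
the five major chronic diseases, then greedy 1:1 nearest-neighbour
matching without replacement on the logit of the score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .config import EPI_FACTORS
from .design import build_covariate_design, drop_collinear, standardize

log = logging.getLogger(__name__)

OUTCOMES = (
    "hyperuricemia", "diabetes", "hyper_ldl_c", "hypertriglyceridemia",
    "hypercholesterolemia", "high_sbp", "high_dbp", "abdominal_obesity",
    "obesity", "hypertension", "hyperlipidemia", "metabolic_syndrome",
)

MAJOR_DISEASES = ("obesity", "hypertension", "diabetes", "hyperuricemia",
                  "hyperlipidemia")


class ClassificationError(ValueError):
    pass


def _ge(series: pd.Series, threshold) -> pd.Series:
    out = (series >= threshold).astype("boolean")
    return out.mask(series.isna())


def _sex_threshold(cohort: pd.DataFrame, male: float, female: float) -> pd.Series:
    sex = cohort["sex"]
    bad = sorted(set(sex.dropna()) - {"M", "F"})
    if bad:
        raise ClassificationError(f"unknown sex codes: {bad}")
    return sex.map({"M": male, "F": female})


def classify_outcomes(cohort: pd.DataFrame) -> pd.DataFrame:
    """Apply the printed diagnostic criteria; returns nullable booleans.

    ``disease_count`` counts confirmed-true labels among the twelve.
    """
    lab = pd.DataFrame(index=cohort.index)
    lab["hyperuricemia"] = _ge(cohort["uric_acid"],
                               _sex_threshold(cohort, 420.0, 360.0))
    lab["diabetes"] = _ge(cohort["hba1c"], 6.5)
    lab["hyper_ldl_c"] = _ge(cohort["ldl_c"], 3.4)
    lab["hypertriglyceridemia"] = _ge(cohort["triglycerides"], 2.3)
    lab["hypercholesterolemia"] = _ge(cohort["total_cholesterol"], 6.2)
    lab["high_sbp"] = _ge(cohort["sbp"], 140.0)
    lab["high_dbp"] = _ge(cohort["dbp"], 90.0)
    lab["abdominal_obesity"] = _ge(cohort["waistline"],
                                   _sex_threshold(cohort, 90.0, 85.0))
    # obesity is the one strict inequality among the printed rules
    lab["obesity"] = (cohort["bmi"] > 28.0).astype("boolean").mask(cohort["bmi"].isna())
    lab["hypertension"] = lab["high_sbp"] | lab["high_dbp"]
    lab["hyperlipidemia"] = (lab["hyper_ldl_c"] | lab["hypertriglyceridemia"]
                             | lab["hypercholesterolemia"])

    mets_parts = lab[["abdominal_obesity", "hypertriglyceridemia",
                      "hypertension", "diabetes"]]
    n_true = (mets_parts == True).sum(axis=1)  # noqa: E712
    n_missing = mets_parts.isna().sum(axis=1)
    mets = pd.Series(pd.NA, index=cohort.index, dtype="boolean")
    mets[n_true >= 3] = True
    mets[(n_true + n_missing) < 3] = False
    lab["metabolic_syndrome"] = mets

    lab["disease_count"] = (lab[list(OUTCOMES)] == True).sum(axis=1)  # noqa: E712
    if "subject_id" in cohort:
        lab.insert(0, "subject_id", cohort["subject_id"])
    return lab


@dataclass
class MatchedSet:
    outcome: str
    case_ids: list
    control_ids: list
    covariates: tuple
    propensity: pd.Series = field(repr=False, default=None)
    model_summary: str = ""

    def pairs(self) -> pd.DataFrame:
        return pd.DataFrame({"case_id": self.case_ids,
                             "control_id": self.control_ids,
                             "outcome": self.outcome})


def _propensity(design: pd.DataFrame, case: np.ndarray):
    X = sm.add_constant(drop_collinear(standardize(design)))
    try:
        res = sm.GLM(case.astype(float), X.astype(float),
                     family=sm.families.Binomial()).fit(maxiter=200)
        if not res.converged:
            raise RuntimeError("not converged")
        return res.predict(X.astype(float)), str(res.summary())
    except Exception:  # quasi-separation etc.: ridge-stabilised fallback
        res = sm.GLM(case.astype(float), X.astype(float),
                     family=sm.families.Binomial()).fit_regularized(alpha=1e-4, L1_wt=0.0)
        return res.predict(X.astype(float)), "regularized logistic propensity model"


def match_controls(cohort: pd.DataFrame, labels: pd.DataFrame, outcome: str,
                   covariates=EPI_FACTORS, *, caliper: float | None = None,
                   distance: str = "logit") -> MatchedSet:
    """Greedy 1:1 propensity matching for one outcome.

    Cases with more than two diseases are excluded (waived for metabolic
    syndrome, as in the published scheme).  The propensity model includes
    the five major chronic diseases for control quality, dropping any that
    is degenerate given case status.  Cases are processed in descending
    score order; distance is |logit(ps) difference| by default (``raw``
    switches to the probability scale).
    """
    if outcome not in OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}")
    lab = labels.set_index("subject_id") if "subject_id" in labels else labels
    coh = cohort.set_index("subject_id") if "subject_id" in cohort else cohort
    y = lab[outcome]

    case_mask = (y == True)  # noqa: E712
    if outcome != "metabolic_syndrome":
        case_mask &= lab["disease_count"] <= 2
    control_mask = (y == False)  # noqa: E712
    pool = coh.index[case_mask | control_mask]
    if case_mask.sum() == 0 or control_mask.sum() == 0:
        raise ValueError(f"{outcome}: need at least one case and one control")
    n_cases, n_controls = int(case_mask.sum()), int(control_mask.sum())
    if n_controls < n_cases:
        raise ValueError(
            f"{outcome}: {n_cases} cases but only {n_controls} eligible controls "
            f"(short by {n_cases - n_controls})")

    design = build_covariate_design(coh.loc[pool].reset_index(), covariates)
    design.index = pool
    for m in MAJOR_DISEASES:
        if m == outcome:
            continue
        ind = (lab.loc[pool, m] == True).astype(float)  # noqa: E712
        # degenerate given case status -> quasi-separation, leave it out
        by_case = ind.groupby(case_mask.loc[pool].to_numpy()).nunique()
        if (by_case <= 1).any():
            continue
        design[f"has_{m}"] = ind

    case = case_mask.loc[pool].to_numpy()
    ps, summary = _propensity(design, case)
    ps = pd.Series(np.asarray(ps), index=pool, name="propensity")
    eps = 1e-12
    score = (np.log(ps.clip(eps, 1 - eps) / (1 - ps.clip(eps, 1 - eps)))
             if distance == "logit" else ps)

    case_ids = score[case].sort_values(ascending=False).index
    ctrl_score = score[~case].copy()
    pairs_case, pairs_ctrl = [], []
    for cid in case_ids:
        d = (ctrl_score - score[cid]).abs()
        best = d.idxmin()
        if caliper is not None and d[best] > caliper:
            continue
        pairs_case.append(cid)
        pairs_ctrl.append(best)
        ctrl_score = ctrl_score.drop(best)
    return MatchedSet(outcome=outcome, case_ids=pairs_case, control_ids=pairs_ctrl,
                      covariates=tuple(covariates), propensity=ps,
                      model_summary=summary)


def covariate_balance(cohort: pd.DataFrame, case_ids, control_ids,
                      covariates=EPI_FACTORS) -> pd.Series:
    """Absolute standardised mean difference per (numeric-encoded) covariate."""
    coh = cohort.set_index("subject_id") if "subject_id" in cohort else cohort
    X = build_covariate_design(coh.reset_index(), covariates)
    X.index = coh.index
    a, b = X.loc[list(case_ids)], X.loc[list(control_ids)]
    pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
    smd = (a.mean() - b.mean()).abs() / pooled.replace(0, np.nan)
    return smd.fillna(0.0)
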