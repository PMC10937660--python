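"""Guidance-value health-risk assessment and dose-risk curves.

Hazard quotients compare each measured serum level with a health-based
guidance concentration (HQ = C_serum / C_guidance; HQ > 1 flags an
exceedance).  Dose-risk curves come from a logistic regression of the
outcome on a restricted cubic spline of log10 concentration (knots at
the 5/35/65/95% quantiles) plus covariates; OR(c) is anchored at a
reference concentration (sample median by default), and the minimum risk
dose is the smallest grid concentration above the anchor whose estimated
OR exceeds 1 for the rest of the grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .config import EPI_FACTORS
from .design import build_covariate_design, drop_collinear, standardize

log = logging.getLogger(__name__)

GUIDANCE_TYPES = ("RfD", "BE", "HBM-II", "BGV")
KNOT_QUANTILES = (0.05, 0.35, 0.65, 0.95)


@dataclass
class DoseRiskCurve:
    chemical: str
    outcome: str
    knots: np.ndarray                 # log10 ng/mL
    grid: pd.DataFrame                # conc, log10_conc, or_, ci_low, ci_high
    reference_concentration: float    # anchor (ng/mL)
    minimum_risk_dose: float          # smallest sustained OR>1 crossing, ng/mL (nan if none)


def hazard_quotients(matrix_values: pd.DataFrame,
                     guidance: pd.DataFrame) -> dict:
    """HQ per subject x chemical plus per-chemical exceedance percentages.

    ``guidance`` has columns ``chemical_id``, ``type``, ``value_ng_ml``.
    Chemicals without a guidance value are skipped with a log entry.
    """
    g = guidance.set_index("chemical_id") if "chemical_id" in guidance else guidance
    bad_type = set(g["type"]) - set(GUIDANCE_TYPES)
    if bad_type:
        raise ValueError(f"unknown guidance types: {sorted(bad_type)}")
    if (g["value_ng_ml"] <= 0).any():
        bad = list(g.index[g["value_ng_ml"] <= 0])
        raise ValueError(f"non-positive guidance values for {bad}")
    have = [c for c in matrix_values.columns if c in g.index]
    skipped = [c for c in matrix_values.columns if c not in g.index]
    if skipped:
        log.info("no guidance value for %d chemicals: %s", len(skipped), skipped)
    hq = matrix_values[have] / g.loc[have, "value_ng_ml"]
    flags = hq > 1.0
    exceed = flags.mean(axis=0) * 100.0
    return {"hq": hq, "exceeds": flags,
            "exceedance_pct": exceed.rename("exceedance_pct"),
            "skipped": skipped}


def rcs_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Restricted (natural) cubic spline basis, linear beyond the end knots.

    With k knots the basis has k-1 columns: x itself plus k-2 truncated
    cubic terms, each normalised by (t_k - t_1)^2.
    """
    x = np.asarray(x, float)
    t = np.asarray(knots, float)
    k = len(t)
    if k < 2:
        return x[:, None]
    cols = [x]
    norm = (t[-1] - t[0]) ** 2
    for j in range(k - 2):
        d = (np.clip(x - t[j], 0, None) ** 3
             - np.clip(x - t[-2], 0, None) ** 3 * (t[-1] - t[j]) / (t[-1] - t[-2])
             + np.clip(x - t[-1], 0, None) ** 3 * (t[-2] - t[j]) / (t[-1] - t[-2]))
        cols.append(d / norm)
    return np.column_stack(cols)


def dose_risk_curve(exposure: pd.Series, outcome: pd.Series,
                    cohort: pd.DataFrame, *, chemical: str = "",
                    outcome_name: str = "", covariates=EPI_FACTORS,
                    n_knots: int = 4, reference: float | None = None,
                    n_grid: int = 100,
                    require_ci: bool = False) -> DoseRiskCurve:
    """Spline logistic dose-risk curve with OR(c) anchored at a reference.

    ``reference=None`` anchors at the sample median concentration.  With
    ``n_knots <= 2`` the spline degenerates to the plain log-linear fit.
    ``require_ci`` demands the CI lower bound (not just the point
    estimate) to exceed 1 when extracting the minimum risk dose.
    """
    keep = exposure.notna() & outcome.notna()
    exposure, outcome, coh = exposure[keep], outcome[keep], cohort.loc[keep]
    x = np.log10(exposure.astype(float).to_numpy())
    if len(np.unique(x)) < max(n_knots, 2):
        raise ValueError("fewer distinct exposure values than knots")
    knots = (np.quantile(x, KNOT_QUANTILES[:n_knots]) if n_knots >= 3
             else np.quantile(x, (0.05, 0.95)))
    if n_knots <= 2:
        knots = knots[:0]  # pure linear term
        B = x[:, None]
    else:
        B = rcs_basis(x, knots)
    Z = standardize(build_covariate_design(coh, covariates))
    Z = drop_collinear(Z) if Z.shape[1] else Z
    X = np.c_[np.ones(len(x)), B, Z.to_numpy(float) if Z.shape[1] else
              np.empty((len(x), 0))]
    y = outcome.astype(float).to_numpy()
    with np.errstate(all="ignore"):
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
    nb = B.shape[1]
    beta_s = res.params[1:1 + nb]
    cov_s = np.asarray(res.cov_params())[1:1 + nb, 1:1 + nb]

    ref = float(np.log10(reference)) if reference is not None else float(np.median(x))
    grid_log = np.union1d(np.linspace(x.min(), x.max(), n_grid), [ref])
    Bg = grid_log[:, None] if nb == 1 else rcs_basis(grid_log, knots)
    Br = (np.array([[ref]]) if nb == 1 else rcs_basis(np.array([ref]), knots))
    D = Bg - Br                      # contrast vs the anchor
    lor = D @ beta_s
    se = np.sqrt(np.einsum("ij,jk,ik->i", D, cov_s, D))
    curve = pd.DataFrame({
        "log10_conc": grid_log,
        "conc": 10.0 ** grid_log,
        "or_": np.exp(lor),
        "ci_low": np.exp(lor - 1.96 * se),
        "ci_high": np.exp(lor + 1.96 * se),
    })
    crit = curve["ci_low"] if require_ci else curve["or_"]
    above = (crit > 1.0) & (curve["log10_conc"] > ref)
    sustained = above[::-1].cumprod()[::-1].astype(bool)  # true iff OR>1 to the end
    mrd = float(curve.loc[sustained, "conc"].iloc[0]) if sustained.any() else np.nan
    return DoseRiskCurve(chemical=chemical, outcome=outcome_name,
                         knots=knots, grid=curve,
                         reference_concentration=float(10.0 ** ref),
                         minimum_risk_dose=mrd)
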