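"""Covariate design-matrix construction shared by the regression modules.

Encoding conventions: binary factors (sex, smoking, drinking) enter as
0/1 indicators; education enters as an ordinal integer score; region,
sampling month and marital status enter as treatment-coded dummies
(first level dropped); age and income stay numeric.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import EDUCATION_LEVELS, EPI_FACTORS

_ORDINAL = {"education": {lvl: i for i, lvl in enumerate(EDUCATION_LEVELS)}}
_BINARY = {"sex": {"M": 1, "F": 0},
           "smoking": {"yes": 1, "no": 0},
           "drinking": {"yes": 1, "no": 0}}
_CATEGORICAL = ("region", "sampling_month", "marital_status")


def build_covariate_design(cohort: pd.DataFrame,
                           covariates=EPI_FACTORS) -> pd.DataFrame:
    """Numeric design matrix (no intercept column) for the given factors.

    Unknown covariate names are taken as generic numeric columns, so extra
    environmental variables (e.g. monthly air-quality values) pass through
    unchanged.
    """
    cols = {}
    for cov in covariates:
        if cov in _BINARY:
            coded = cohort[cov].map(_BINARY[cov])
            if coded.isna().any() and cohort[cov].notna().any():
                bad = sorted(set(cohort.loc[coded.isna(), cov].dropna()))
                raise ValueError(f"unknown codes for {cov}: {bad}")
            cols[cov] = coded.astype(float)
        elif cov in _ORDINAL:
            cols[cov] = cohort[cov].map(_ORDINAL[cov]).astype(float)
        elif cov in _CATEGORICAL:
            dummies = pd.get_dummies(cohort[cov], prefix=cov, drop_first=True,
                                     dtype=float)
            for name in dummies.columns:
                cols[name] = dummies[name]
        else:
            cols[cov] = pd.to_numeric(cohort[cov], errors="raise").astype(float)
    out = pd.DataFrame(cols, index=cohort.index)
    # constant columns carry no information and break ML fits
    keep = [c for c in out.columns if out[c].nunique(dropna=True) > 1]
    return out[keep]


def standardize(X: pd.DataFrame) -> pd.DataFrame:
    """Center/scale columns (z-scores).  Used for nuisance covariates:
    rescaling them leaves the exposure coefficient untouched but keeps
    Newton-type optimisers well conditioned (income spans 1e5)."""
    mu = X.mean()
    sd = X.std(ddof=0).replace(0, 1.0)
    return (X - mu) / sd


def drop_collinear(X: pd.DataFrame, tol: float = 1e-9) -> pd.DataFrame:
    """Drop trailing columns until the design has full column rank."""
    keep: list[str] = []
    for col in X.columns:
        trial = X[keep + [col]].to_numpy(float)
        if np.linalg.matrix_rank(np.c_[np.ones(len(trial)), trial], tol=tol) == \
                len(keep) + 2:
            keep.append(col)
    return X[keep]
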