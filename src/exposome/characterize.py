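"""Exposure characterisation statistics.

Detection frequencies (flag-based, so LOQ imputation never changes
them), the high-frequency rule (> 50% in at least one region, strict),
geometric means with log-scale t confidence intervals, stratified group
differences with Benjamini-Hochberg control and the 0.8/1.3 fold-change
screen, partial Spearman correlations with the remaining factors as
confounders, variance partitioning over the epidemiological factors, and
PCA of the standardised log10 exposure matrix.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .design import build_covariate_design
from .quantify import ConcentrationMatrix

HIGH_FREQUENCY_CUTOFF = 50.0   # percent, strict >
FOLD_CHANGE_BAND = (0.8, 1.3)  # notable outside this band


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def detection_frequency(matrix: ConcentrationMatrix,
                        regions: pd.Series) -> pd.DataFrame:
    """Overall and per-region detection frequency (%) per chemical.

    Detection means measured and not below-LOQ; cells never measured
    (no batch) do not enter the denominator.  A chemical measured in zero
    subjects gets NaN and an ``undefined`` flag.
    """
    measured = matrix.batch.notna()
    detected = measured & ~matrix.below_loq
    reg = regions.reindex(matrix.values.index)

    def freq(det: pd.DataFrame, meas: pd.DataFrame) -> pd.Series:
        n = meas.sum(axis=0)
        return pd.Series(np.where(n > 0, det.sum(axis=0) / n * 100.0, np.nan),
                         index=det.columns)

    out = pd.DataFrame({"freq_total": freq(detected, measured)})
    for r in sorted(reg.dropna().unique()):
        m = reg == r
        out[f"freq_{r}"] = freq(detected.loc[m.to_numpy()], measured.loc[m.to_numpy()])
    region_cols = [c for c in out.columns if c.startswith("freq_") and c != "freq_total"]
    out["freq_region_max"] = out[region_cols].max(axis=1)
    out["high_frequency"] = out["freq_region_max"] > HIGH_FREQUENCY_CUTOFF
    out["undefined"] = out["freq_total"].isna()
    return out


def select_high_frequency(summary: pd.DataFrame) -> list:
    """Chemicals whose detection frequency exceeds 50% in some region."""
    return list(summary.index[summary["high_frequency"].fillna(False)])


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def geometric_summary(values) -> dict:
    """Geometric mean, 95% log-scale t CI, and median of a positive vector."""
    v = np.asarray(values, float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("no finite values")
    if (v <= 0).any():
        raise ValueError("non-positive values: run below-LOQ imputation first")
    logs = np.log(v)
    m, n = logs.mean(), logs.size
    if n > 1:
        se = logs.std(ddof=1) / np.sqrt(n)
        half = stats.t.ppf(0.975, n - 1) * se
    else:
        half = 0.0
    return {"gm": float(np.exp(m)),
            "ci_low": float(np.exp(m - half)),
            "ci_high": float(np.exp(m + half)),
            "median": float(np.median(v)),
            "n": int(n)}


def concentration_table(matrix: ConcentrationMatrix,
                        regions: pd.Series) -> pd.DataFrame:
    """Per-chemical atlas row: detection frequencies, GM (95% CI), median."""
    det = detection_frequency(matrix, regions)
    rows = {}
    for chem in matrix.values.columns:
        v = matrix.values[chem].dropna()
        g = geometric_summary(v) if len(v) else dict(
            gm=np.nan, ci_low=np.nan, ci_high=np.nan, median=np.nan, n=0)
        rows[chem] = g
    gm = pd.DataFrame(rows).T
    out = det[["freq_total", "freq_region_max", "high_frequency"]].join(gm)
    # a median below the LOQ everywhere is reported as censored
    med_detected = (det["freq_total"] > 50.0)
    out["median_censored"] = ~med_detected
    return out


# ---------------------------------------------------------------------------
# group differences
# ---------------------------------------------------------------------------

def stratified_differences(matrix_values: pd.DataFrame, grouping: pd.Series,
                           group1, group2) -> pd.DataFrame:
    """Fold change of geometric means, rank-sum p, and BH q per chemical.

    ``notable`` requires q < 0.05 and a fold change outside [0.8, 1.3].
    """
    g = grouping.reindex(matrix_values.index)
    m1, m2 = (g == group1).to_numpy(), (g == group2).to_numpy()
    if m1.sum() < 3 or m2.sum() < 3:
        raise ValueError("each group needs n >= 3")
    rows = []
    for chem in matrix_values.columns:
        v = matrix_values[chem]
        a, b = v[m1].dropna(), v[m2].dropna()
        if a.empty or b.empty:
            raise ValueError(f"{chem}: empty group")
        fc = np.exp(np.log(a).mean() - np.log(b).mean())
        p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        rows.append({"chemical_id": chem, "fold_change": float(fc), "p": float(p)})
    out = pd.DataFrame(rows).set_index("chemical_id")
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    out["notable"] = (out["q"] < 0.05) & ((out["fold_change"] < FOLD_CHANGE_BAND[0])
                                          | (out["fold_change"] > FOLD_CHANGE_BAND[1]))
    return out


# ---------------------------------------------------------------------------
# partial Spearman
# ---------------------------------------------------------------------------

def _residualise(y: np.ndarray, Z: np.ndarray) -> np.ndarray:
    X = np.c_[np.ones(len(y)), Z]
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def partial_spearman(matrix_values: pd.DataFrame, cohort: pd.DataFrame,
                     factor: str, confounders) -> pd.DataFrame:
    """Partial Spearman rho between one factor and each chemical.

    All variables are rank-transformed; factor and chemical ranks are
    residualised on the confounder ranks by least squares and the Pearson
    correlation of the residuals is returned, with a t-approximation p and
    BH q across chemicals.
    """
    f = build_covariate_design(cohort, [factor])
    if f.shape[1] == 0:
        raise ValueError(f"factor {factor!r} is constant: correlation undefined")
    if f.shape[1] > 1:
        raise ValueError(f"factor {factor!r} is not numeric or ordinal-codable")
    Z = build_covariate_design(cohort, confounders)
    n, k = len(cohort), Z.shape[1]
    if n <= k + 2:
        raise ValueError("n must exceed #confounders + 2")
    fr = stats.rankdata(f.iloc[:, 0])
    Zr = np.column_stack([stats.rankdata(Z[c]) for c in Z.columns]) if k else \
        np.empty((n, 0))
    f_res = _residualise(fr.astype(float), Zr)
    rows = []
    idx = matrix_values.index
    for chem in matrix_values.columns:
        yr = stats.rankdata(matrix_values[chem].reindex(idx)).astype(float)
        y_res = _residualise(yr, Zr)
        denom = np.sqrt((f_res ** 2).sum() * (y_res ** 2).sum())
        rho = float((f_res * y_res).sum() / denom) if denom > 0 else np.nan
        df = n - 2 - k
        if np.isfinite(rho) and abs(rho) < 1:
            t = rho * np.sqrt(df / (1 - rho ** 2))
            p = 2 * stats.t.sf(abs(t), df)
        else:
            p = 0.0 if np.isfinite(rho) else np.nan
        rows.append({"chemical_id": chem, "rho": rho, "p": p})
    out = pd.DataFrame(rows).set_index("chemical_id")
    out["q"] = multipletests(out["p"].fillna(1.0), method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# variance partitioning
# ---------------------------------------------------------------------------

def _adjusted_r2_matrix(Y: np.ndarray, X: np.ndarray) -> float:
    """Mean adjusted R^2 of column-wise OLS of Y on X (with intercept)."""
    n, p = X.shape
    Xd = np.c_[np.ones(n), X]
    beta, *_ = np.linalg.lstsq(Xd, Y, rcond=None)
    resid = Y - Xd @ beta
    sse = (resid ** 2).sum(axis=0)
    sst = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(sst > 0, 1 - sse / sst, 0.0)
    dof = n - p - 1
    if dof <= 0:
        return float(np.mean(r2))
    adj = 1 - (1 - r2) * (n - 1) / dof
    return float(np.mean(adj))


def variance_partition(matrix_values: pd.DataFrame, cohort: pd.DataFrame,
                       factors) -> pd.DataFrame:
    """Fraction of exposure variance attributable to each factor.

    Exposures are log10-transformed and column-standardised.  For each
    factor both the marginal fraction (adjusted R^2 of that factor alone,
    averaged over chemicals) and the unique fraction (joint adjusted R^2
    minus the adjusted R^2 without the factor) are reported, plus the
    joint row for all factors together.
    """
    Y = np.log10(matrix_values.to_numpy(float))
    Y = (Y - Y.mean(axis=0)) / np.where(Y.std(axis=0) > 0, Y.std(axis=0), 1.0)
    designs = {f: build_covariate_design(cohort, [f]).to_numpy(float)
               for f in factors}
    X_all = np.column_stack([designs[f] for f in factors if designs[f].shape[1]])
    joint = _adjusted_r2_matrix(Y, X_all) if X_all.size else 0.0
    rows = []
    for f in factors:
        Xf = designs[f]
        marginal = _adjusted_r2_matrix(Y, Xf) if Xf.shape[1] else 0.0
        others = [designs[g] for g in factors if g != f and designs[g].shape[1]]
        if others and Xf.shape[1]:
            without = _adjusted_r2_matrix(Y, np.column_stack(others))
            unique = joint - without
        else:
            unique = marginal
        rows.append({"factor": f, "marginal": marginal, "unique": unique})
    out = pd.DataFrame(rows).set_index("factor")
    out.loc["__joint__"] = {"marginal": joint, "unique": joint}
    return out


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca_scores(matrix_values: pd.DataFrame, n_components: int | None = None,
               scale: bool = True, log: bool = True):
    """PCA of the (log10, standardised) exposure matrix via SVD.

    Returns (scores, loadings, explained_variance_ratio).  Zero-variance
    columns are dropped with a warning; scores @ loadings.T reconstructs
    the standardised matrix.
    """
    import warnings

    X = matrix_values.to_numpy(float)
    if log:
        if (X <= 0).any():
            raise ValueError("non-positive values: impute before PCA")
        X = np.log10(X)
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.all():
        dropped = list(matrix_values.columns[~keep])
        warnings.warn(f"dropping zero-variance columns: {dropped}")
    cols = matrix_values.columns[keep]
    X = X[:, keep]
    X = X - X.mean(axis=0)
    if scale:
        X = X / X.std(axis=0)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    # sign convention: largest-magnitude loading positive
    signs = np.sign(Vt[np.arange(Vt.shape[0]), np.abs(Vt).argmax(axis=1)])
    Vt = Vt * signs[:, None]
    U = U * signs[None, :]
    k = n_components or len(S)
    scores = pd.DataFrame(U[:, :k] * S[:k], index=matrix_values.index,
                          columns=[f"PC{i + 1}" for i in range(k)])
    loadings = pd.DataFrame(Vt[:k].T, index=cols,
                            columns=[f"PC{i + 1}" for i in range(k)])
    explained = S ** 2 / (S ** 2).sum()
    return scores, loadings, pd.Series(explained[:k],
                                       index=[f"PC{i + 1}" for i in range(k)])
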