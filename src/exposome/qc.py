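"""Quality-control metrics and batch-effect diagnostics.

Acceptance logic follows targeted-panel convention: per-chemical RSD of
repeated QC injections must stay below 30% (stable detection) and mean
recovery at each spike level must fall within 80-120% (accurate
detection).  Batch effects are summarised by a one-way ANOVA R^2 of log10
QC values across batches, averaged over chemicals, alongside PCA scores
of the QC matrix for plotting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

RSD_LIMIT = 30.0
RECOVERY_BAND = (80.0, 120.0)


@dataclass
class QCReport:
    precision: pd.DataFrame   # chemical, platform, level, rsd_pct, pass_rsd
    recovery: pd.DataFrame    # chemical, platform, level, recovery_pct, pass_recovery
    summary: pd.DataFrame     # platform, frac_pass_rsd, frac_pass_recovery


def qc_metrics(qc_concentrations: pd.DataFrame) -> QCReport:
    """Precision (RSD) and recovery from quantified QC samples.

    Input is the long QC table from quantification (``chemical_id``,
    ``platform``, ``nominal``, ``conc``).  RSD is sd/mean x 100 over the
    QCs of a chemical at each spike level; recovery is mean measured /
    nominal x 100.  Strict inequalities as printed: RSD < 30,
    80 <= recovery <= 120.  A chemical with zero mean is flagged
    (RSD undefined).
    """
    qc = qc_concentrations.copy()
    if qc.empty:
        empty = pd.DataFrame()
        return QCReport(empty, empty, empty)
    grouped = qc.groupby(["chemical_id", "platform", "nominal"], sort=True)["conc"]
    stats = grouped.agg(n="count", mean="mean", sd=lambda v: v.std(ddof=1)).reset_index()
    if (stats["n"] < 2).any():
        under = stats.loc[stats["n"] < 2, "chemical_id"].unique()
        raise ValueError(f"need >= 2 QC measurements per chemical/level; short: {list(under)}")
    prec = stats.rename(columns={"nominal": "level"}).copy()
    zero_mean = prec["mean"] == 0
    prec["rsd_pct"] = np.where(zero_mean, np.nan, prec["sd"] / prec["mean"] * 100.0)
    prec["flag_undefined"] = zero_mean
    prec["pass_rsd"] = prec["rsd_pct"] < RSD_LIMIT
    prec = prec[["chemical_id", "platform", "level", "rsd_pct", "pass_rsd",
                 "flag_undefined"]]

    rec = stats.rename(columns={"nominal": "level"}).copy()
    rec["recovery_pct"] = rec["mean"] / rec["level"] * 100.0
    rec["pass_recovery"] = rec["recovery_pct"].between(*RECOVERY_BAND)
    rec = rec[["chemical_id", "platform", "level", "recovery_pct", "pass_recovery"]]

    per_chem = (prec.groupby(["chemical_id", "platform"])["pass_rsd"].all()
                .to_frame("pass_rsd")
                .join(rec.groupby(["chemical_id", "platform"])["pass_recovery"].all()))
    summary = (per_chem.groupby("platform")
               .agg(frac_pass_rsd=("pass_rsd", "mean"),
                    frac_pass_recovery=("pass_recovery", "mean"))
               .reset_index())
    return QCReport(precision=prec, recovery=rec, summary=summary)


def _anova_r2(values: np.ndarray, groups: np.ndarray) -> float:
    """Between-group SS / total SS of one vector; 0 when total SS is 0."""
    v = np.asarray(values, float)
    keep = np.isfinite(v)
    v, g = v[keep], np.asarray(groups)[keep]
    if v.size == 0:
        return np.nan
    grand = v.mean()
    sst = np.sum((v - grand) ** 2)
    # variance at float-epsilon level is numerically zero, not structure
    if sst <= v.size * (1e-12 * max(1.0, abs(grand))) ** 2:
        return 0.0
    ssb = 0.0
    for lvl in pd.unique(g):
        sub = v[g == lvl]
        ssb += sub.size * (sub.mean() - grand) ** 2
    return float(ssb / sst)


def batch_effect_metric(qc_matrix: pd.DataFrame, batches: pd.Series) -> pd.Series:
    """Per-chemical ANOVA R^2 of log10 QC values across batches.

    ``qc_matrix`` is QC samples x chemicals (positive values); ``batches``
    labels each QC row.  Values are log10-transformed first, so the metric
    is invariant to rescaling any chemical.
    """
    b = np.asarray(batches)
    if len(pd.unique(b)) < 2:
        raise ValueError("batch-effect metric undefined with a single batch")
    counts = pd.Series(b).value_counts()
    if (counts < 2).any():
        raise ValueError("each batch needs >= 2 QC samples")
    out = {}
    for chem in qc_matrix.columns:
        v = qc_matrix[chem].to_numpy(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            lv = np.where(v > 0, np.log10(np.where(v > 0, v, 1.0)), np.nan)
        out[chem] = _anova_r2(lv, b)
    return pd.Series(out, name="batch_r2")


def pca_qc_scores(qc_matrix: pd.DataFrame, n_components: int = 2) -> pd.DataFrame:
    """PCA scores of the (log10, column-standardised) QC matrix."""
    from .characterize import pca_scores
    scores, _, _ = pca_scores(qc_matrix, n_components=n_components)
    return scores


def batch_effect_assessment(qc_before: pd.DataFrame, qc_after: pd.DataFrame,
                            batches: pd.Series) -> dict:
    """Compare the batch-effect metric before vs after correction.

    ``qc_before`` is typically raw QC analyte areas, ``qc_after`` the
    IS-corrected batch-specifically quantified QC concentrations; both are
    QC samples x chemicals aligned with ``batches``.
    """
    before = batch_effect_metric(qc_before, batches)
    after = batch_effect_metric(qc_after, batches)
    return {
        "metric_before": float(before.mean()),
        "metric_after": float(after.mean()),
        "per_chemical": pd.DataFrame({"before": before, "after": after}),
        "scores_before": pca_qc_scores(qc_before),
        "scores_after": pca_qc_scores(qc_after),
    }
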