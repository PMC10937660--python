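"""Internal-standard calibrated quantification of peak tables.

The engine turns long-format peak tables into a subjects x chemicals
concentration matrix:

1. pick the internal standard per analyte (static nearest retention time
   on the GC platform; smallest QC RSD after correction on the LC
   platform; external-standard fallback when no candidate exists);
2. per (chemical, batch), fit a 1/x-weighted linear calibration of
   relative response (analyte area / IS area) on nominal concentration;
3. estimate the LOQ per (chemical, batch) as the lowest ladder level with
   chromatographic S/N > 10;
4. back-calculate study and QC samples through their own batch's curve;
5. flag values below the batch LOQ and impute them as LOQ / sqrt(2).

Because analyte and matched IS share instrument drift, the area ratio
cancels it; per-batch curves remove what the IS does not.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .config import Panel

log = logging.getLogger(__name__)

MIN_CALIBRATOR_LEVELS = 5
SN_THRESHOLD = 10.0
ACCURACY_BAND = (80.0, 120.0)


class SingularDesignError(ValueError):
    """All calibrator concentrations identical: no line can be fitted."""


@dataclass
class CalibrationFit:
    chemical_id: str
    batch: str
    slope: float = np.nan
    intercept: float = np.nan
    r2: float = np.nan
    loq: float = np.nan
    weighting: str = "1/x"
    is_id: str = "external"
    ok: bool = False
    reason: str = ""


@dataclass
class ConcentrationMatrix:
    """Subjects x chemicals concentrations with below-LOQ flags.

    ``below_loq`` stays fixed through imputation so detection frequencies
    are always computed from the original flags.  ``loq`` and ``batch``
    record, per cell, the LOQ and batch of the curve that quantified it.
    """

    values: pd.DataFrame
    below_loq: pd.DataFrame
    loq: pd.DataFrame
    batch: pd.DataFrame
    imputed: bool = False


@dataclass
class QuantificationResult:
    matrix: ConcentrationMatrix
    fits: dict                       # (chemical_id, batch) -> CalibrationFit
    is_assignment: pd.Series         # chemical -> is_id or "external"
    qc_concentrations: pd.DataFrame  # long: sample, batch, platform, chemical, nominal, conc
    accuracy: pd.DataFrame = field(default_factory=pd.DataFrame)

    def fits_frame(self) -> pd.DataFrame:
        rows = [vars(f).copy() for f in self.fits.values()]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def fit_calibration(conc, response, weighting: str = "1/x",
                    chemical_id: str = "", batch: str = "",
                    is_id: str = "external") -> CalibrationFit:
    """1/x-weighted linear fit of relative response on concentration.

    The zero-concentration calibrator is excluded (its weight is
    undefined); r2 is computed on the weighted scale, consistent with the
    1/x objective.  Fewer than five distinct positive levels flags the
    curve unquantifiable rather than raising.
    """
    if weighting != "1/x":
        raise ValueError(f"unsupported weighting {weighting!r}")
    x = np.asarray(conc, float)
    y = np.asarray(response, float)
    keep = np.isfinite(x) & np.isfinite(y) & (x > 0)
    x, y = x[keep], y[keep]
    fit = CalibrationFit(chemical_id=chemical_id, batch=batch, is_id=is_id)
    if len(x) and np.ptp(x) == 0:
        raise SingularDesignError("all calibrator concentrations identical")
    if len(np.unique(x)) < MIN_CALIBRATOR_LEVELS:
        fit.reason = "insufficient_levels"
        return fit
    res = sm.WLS(y, sm.add_constant(x), weights=1.0 / x).fit()
    fit.intercept, fit.slope = float(res.params[0]), float(res.params[1])
    fit.r2 = float(res.rsquared)
    if fit.slope <= 0:
        fit.reason = "nonpositive_slope"
        return fit
    fit.ok = True
    return fit


def estimate_loq(levels, areas, noise_sd: float) -> float:
    """Lowest ladder concentration whose mean area exceeds 10x the noise.

    Mirrors the chromatographic S/N > 10 rule (strict inequality).  Returns
    +inf when no level qualifies, flagging the chemical undetectable in
    that batch.
    """
    levels = np.asarray(levels, float)
    areas = np.asarray(areas, float)
    if levels.size == 0:
        raise ValueError("empty calibration ladder")
    if not (noise_sd > 0):
        raise ValueError("noise_sd must be positive")
    tab = pd.DataFrame({"level": levels, "area": areas})
    tab = tab[tab["level"] > 0]
    mean_area = tab.groupby("level")["area"].mean().sort_index()
    sn = mean_area / noise_sd
    passing = sn.index[sn > SN_THRESHOLD]
    return float(passing[0]) if len(passing) else math.inf


def select_internal_standard(chemical_id: str, candidates, mode: str, *,
                             panel: Panel | None = None,
                             areas: pd.DataFrame | None = None,
                             meta: pd.DataFrame | None = None) -> str:
    """Choose the internal standard for one analyte.

    ``gc_rt``: candidate with minimum |retention-time difference| (ties go
    to the earlier-eluting IS).  ``lc_min_rsd``: for each candidate, the
    QC samples are IS-corrected, quantified through their own batch's
    1/x-weighted curve, and the candidate minimising the QC concentration
    RSD (per spike level, averaged) wins; ties break by candidate order.

    ``areas`` is a samples x compounds wide table and ``meta`` carries
    ``role``, ``batch`` and ``nominal`` per sample (lc mode only).
    """
    candidates = list(candidates)
    if not candidates:
        log.warning("%s: no IS candidates; achieved by external standard method",
                    chemical_id)
        return "external"
    if mode == "gc_rt":
        if panel is None:
            raise ValueError("gc_rt mode requires the panel (retention times)")
        rt = panel.chemical(chemical_id).rt
        return min(candidates,
                   key=lambda i: (abs(panel.internal_standard(i).rt - rt),
                                  panel.internal_standard(i).rt))
    if mode != "lc_min_rsd":
        raise ValueError(f"unknown IS selection mode {mode!r}")
    if areas is None or meta is None:
        raise ValueError("lc_min_rsd mode requires areas and sample metadata")
    qc_mask = meta["role"] == "qc"
    if meta.loc[qc_mask, "batch"].nunique() < 2:
        raise ValueError("lc_min_rsd requires QC records spanning >= 2 batches")

    best_id, best_rsd = None, math.inf
    for cand in candidates:
        ratio = areas[chemical_id] / areas[cand]
        qc_conc = []
        for b, grp in meta.groupby("batch", sort=True):
            cal = grp.index[(grp["role"] == "calibrator")]
            fit = fit_calibration(meta.loc[cal, "nominal"], ratio.loc[cal],
                                  chemical_id=chemical_id, batch=str(b), is_id=cand)
            if not fit.ok:
                continue
            qs = grp.index[grp["role"] == "qc"]
            conc = (ratio.loc[qs] - fit.intercept) / fit.slope
            qc_conc.append(pd.DataFrame({"nominal": meta.loc[qs, "nominal"],
                                         "conc": conc}))
        if not qc_conc:
            continue
        allqc = pd.concat(qc_conc)
        rsds = allqc.groupby("nominal")["conc"].agg(
            lambda v: v.std(ddof=1) / v.mean() if v.mean() != 0 else math.inf)
        rsd = float(rsds.mean())
        if rsd < best_rsd - 1e-15:
            best_id, best_rsd = cand, rsd
    if best_id is None:
        log.warning("%s: no candidate produced usable QC fits; external standard",
                    chemical_id)
        return "external"
    return best_id


def impute_below_loq(matrix: ConcentrationMatrix,
                     ceiling_loq: float | None = None) -> ConcentrationMatrix:
    """Replace below-LOQ cells by their batch LOQ / sqrt(2).

    Cells whose batch LOQ is +inf (undetectable chemical in that batch)
    use ``ceiling_loq`` when given; otherwise they remain missing and are
    reported as 0% detected rather than dropped study-wide.  Flags are
    preserved so detection frequencies never change under imputation.
    """
    vals = matrix.values.copy()
    loq = matrix.loq
    fill = loq / math.sqrt(2.0)
    if ceiling_loq is not None:
        fill = fill.where(np.isfinite(loq), ceiling_loq / math.sqrt(2.0))
    else:
        fill = fill.where(np.isfinite(loq))
    mask = matrix.below_loq.astype(bool)
    vals = vals.where(~mask, fill)
    return ConcentrationMatrix(values=vals, below_loq=matrix.below_loq.copy(),
                               loq=matrix.loq.copy(), batch=matrix.batch.copy(),
                               imputed=True)


def evaluate_curve_accuracy(qc_concentrations: pd.DataFrame,
                            levels=None) -> pd.DataFrame:
    """Per-curve accuracy at the spiked levels: measured/nominal x 100.

    Pass iff within [80, 120]%.  Levels absent from a batch are simply not
    evaluated.
    """
    qc = qc_concentrations
    if levels is not None:
        qc = qc[qc["nominal"].isin(list(levels))]
    if qc.empty:
        return pd.DataFrame(columns=["chemical_id", "batch", "nominal",
                                     "accuracy_pct", "pass"])
    out = (qc.groupby(["chemical_id", "batch", "nominal"], sort=True)["conc"]
           .mean().reset_index())
    out["accuracy_pct"] = out["conc"] / out["nominal"] * 100.0
    out["pass"] = out["accuracy_pct"].between(*ACCURACY_BAND)
    return out.drop(columns="conc")


# ---------------------------------------------------------------------------
# study-level orchestration
# ---------------------------------------------------------------------------

def _pivot_platform(table: pd.DataFrame):
    """Wide samples x compounds area table plus per-sample metadata."""
    areas = table.pivot_table(index="sample_id", columns="chemical_id",
                              values="area", aggfunc="first")
    meta = (table[["sample_id", "role", "batch", "nominal_conc_ng_ml"]]
            .drop_duplicates("sample_id").set_index("sample_id")
            .rename(columns={"nominal_conc_ng_ml": "nominal"}))
    meta = meta.loc[areas.index]
    return areas, meta


def _relative_response(areas: pd.DataFrame, table: pd.DataFrame,
                       chemical_id: str, is_id: str) -> pd.Series:
    if is_id == "external":
        return areas[chemical_id]
    if is_id in areas.columns:
        return areas[chemical_id] / areas[is_id]
    # fall back to the embedded is_area column (no dedicated IS rows)
    sub = table[table["chemical_id"] == chemical_id].set_index("sample_id")
    return (sub["area"] / sub["is_area"]).reindex(areas.index)


def quantify_study(peak_tables: dict, panel: Panel, noise_sd,
                   *, is_mode: dict | None = None,
                   loq_override=None) -> QuantificationResult:
    """Full quantification of a study's peak tables.

    ``noise_sd`` maps chemical -> chromatographic noise (area units) for
    the S/N-based LOQ.  ``is_mode`` optionally overrides the per-platform
    selection rule (defaults: GC -> gc_rt, LC -> lc_min_rsd).
    ``loq_override`` maps chemical -> study-level LOQ replacing the
    per-batch estimate.
    """
    noise_sd = pd.Series(noise_sd)
    is_mode = {"GC": "gc_rt", "LC": "lc_min_rsd", **(is_mode or {})}
    fits: dict = {}
    assignment: dict[str, str] = {}
    qc_rows = []
    conc_frames, flag_frames, loq_frames, batch_frames = [], [], [], []

    for platform, table in peak_tables.items():
        chems = [c.chemical_id for c in panel.by_platform(platform)]
        chems = [c for c in chems if c in set(table["chemical_id"])]
        if not chems:
            continue
        areas, meta = _pivot_platform(table)
        batches = sorted(meta["batch"].unique())
        study_samples = meta.index[meta["role"] == "study"]

        conc_m = pd.DataFrame(np.nan, index=study_samples, columns=chems)
        flag_m = pd.DataFrame(False, index=study_samples, columns=chems)
        loq_m = pd.DataFrame(np.nan, index=study_samples, columns=chems)
        batch_m = pd.DataFrame(meta.loc[study_samples, "batch"].to_numpy()[:, None]
                               .repeat(len(chems), axis=1),
                               index=study_samples, columns=chems)

        for chem in chems:
            cands = list(panel.chemical(chem).candidate_is)
            try:
                isid = select_internal_standard(
                    chem, cands, is_mode[platform], panel=panel,
                    areas=areas, meta=meta)
            except ValueError:
                isid = select_internal_standard(chem, cands, "gc_rt", panel=panel)
            assignment[chem] = isid
            ratio = _relative_response(areas, table, chem, isid)

            for b in batches:
                in_b = meta["batch"] == b
                cal_idx = meta.index[in_b & (meta["role"] == "calibrator")]
                fit = fit_calibration(meta.loc[cal_idx, "nominal"],
                                      ratio.loc[cal_idx],
                                      chemical_id=chem, batch=b, is_id=isid)
                if loq_override is not None and chem in loq_override:
                    fit.loq = float(loq_override[chem])
                else:
                    fit.loq = estimate_loq(meta.loc[cal_idx, "nominal"],
                                           areas.loc[cal_idx, chem],
                                           float(noise_sd[chem]))
                fits[(chem, b)] = fit

                members = meta.index[in_b & (meta["role"] == "study")]
                if len(members):
                    if fit.ok:
                        c = (ratio.loc[members] - fit.intercept) / fit.slope
                        below = (c < fit.loq) | (c <= 0) | ~np.isfinite(c)
                        conc_m.loc[members, chem] = c.where(~below)
                        flag_m.loc[members, chem] = below
                        loq_m.loc[members, chem] = fit.loq
                    else:
                        flag_m.loc[members, chem] = False
                        conc_m.loc[members, chem] = np.nan
                qs = meta.index[in_b & (meta["role"] == "qc")]
                if len(qs) and fit.ok:
                    cq = (ratio.loc[qs] - fit.intercept) / fit.slope
                    qc_rows.append(pd.DataFrame({
                        "sample_id": qs, "batch": b, "platform": platform,
                        "chemical_id": chem,
                        "nominal": meta.loc[qs, "nominal"].to_numpy(),
                        "conc": cq.to_numpy(),
                    }))
        conc_frames.append(conc_m)
        flag_frames.append(flag_m)
        loq_frames.append(loq_m)
        batch_frames.append(batch_m)

    values = pd.concat(conc_frames, axis=1) if conc_frames else pd.DataFrame()
    below = (pd.concat(flag_frames, axis=1).astype("boolean").fillna(False)
             .astype(bool)) if flag_frames else pd.DataFrame()
    loq = pd.concat(loq_frames, axis=1) if loq_frames else pd.DataFrame()
    batch = pd.concat(batch_frames, axis=1) if batch_frames else pd.DataFrame()
    values = values.sort_index()
    below = below.reindex(values.index).astype("boolean").fillna(False).astype(bool)
    loq = loq.reindex(values.index)
    batch = batch.reindex(values.index)

    matrix = ConcentrationMatrix(values=values, below_loq=below, loq=loq,
                                 batch=batch, imputed=False)
    qc_concentrations = (pd.concat(qc_rows, ignore_index=True)
                         if qc_rows else pd.DataFrame(
        columns=["sample_id", "batch", "platform", "chemical_id", "nominal", "conc"]))
    accuracy = evaluate_curve_accuracy(qc_concentrations)
    return QuantificationResult(matrix=matrix, fits=fits,
                                is_assignment=pd.Series(assignment, name="is_id"),
                                qc_concentrations=qc_concentrations,
                                accuracy=accuracy)
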