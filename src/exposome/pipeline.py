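"""End-to-end orchestration: simulate -> quantify -> qc -> outcomes ->
characterize -> associations -> mixtures -> risk.

Each stage writes plain CSV outputs under the run directory and registers
them in a machine-readable manifest (seed, stage order, SHA-256 of every
file), so a rerun with the same configuration is byte-identical and
verifiably so.  A stage failure aborts the run naming the stage; outputs
of completed stages are preserved.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import associations as assoc_mod
from . import characterize as char_mod
from . import mixtures as mix_mod
from . import outcomes as out_mod
from . import qc as qc_mod
from . import risk as risk_mod
from .config import EPI_FACTORS, StudyConfig
from .quantify import impute_below_loq, quantify_study
from .simulate import StudyBundle, generate_study, read_study_bundle, write_study_bundle

log = logging.getLogger(__name__)

STAGES = ("simulate", "quantify", "qc", "outcomes", "characterize",
          "associations", "mixtures", "risk")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    out_dir: str
    seed: int = 0
    simulate: bool = True
    input_dir: str | None = None        # bundle directory when simulate=False
    study: dict = field(default_factory=dict)   # StudyConfig overrides
    stages: tuple = STAGES
    analysis_outcomes: tuple = ("hyperuricemia",)
    n_boot: int = 100
    wqs_split: float = 0.4
    n_knots: int = 4
    caliper: float | None = None
    mixture_model: str = "wqs"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def study_config(self) -> StudyConfig:
        from .config import BatchLayout
        overrides = dict(self.study)
        for key in ("batch_layout_gc", "batch_layout_lc"):
            if isinstance(overrides.get(key), dict):
                overrides[key] = BatchLayout(**overrides[key])
        overrides.setdefault("outcome_effects", _default_effects(self.analysis_outcomes))
        cfg = StudyConfig(seed=self.seed, **overrides)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise PipelineError(f"unknown stages: {sorted(unknown)}")
        if not self.simulate and "quantify" in self.stages:
            if not self.input_dir:
                raise PipelineError(
                    "missing input: peak tables (set input_dir or enable simulate)")
            for fname in ("peaks_gc.csv", "peaks_lc.csv"):
                if not os.path.exists(os.path.join(self.input_dir, fname)):
                    raise PipelineError(f"missing input: {fname} in {self.input_dir}")


def _default_effects(outcome_names) -> dict:
    effects = {}
    for i, name in enumerate(outcome_names):
        effects[name] = {"GC_001": 0.5, "LC_001": 0.4,
                         "_intercept": -0.8 - 0.2 * i}
    return effects


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in order; returns the run manifest."""
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    manifest = {"seed": config.seed, "stages": [], "outputs": {}}
    state: dict = {}

    def register(stage: str, *paths):
        for p in paths:
            rel = os.path.relpath(p, config.out_dir)
            manifest["outputs"][rel] = _sha256(p)
        if stage not in manifest["stages"]:
            manifest["stages"].append(stage)

    runner = {
        "simulate": _stage_simulate, "quantify": _stage_quantify,
        "qc": _stage_qc, "outcomes": _stage_outcomes,
        "characterize": _stage_characterize, "associations": _stage_associations,
        "mixtures": _stage_mixtures, "risk": _stage_risk,
    }
    for stage in STAGES:
        if stage not in config.stages:
            continue
        try:
            runner[stage](config, state, register)
        except Exception as exc:
            _write_manifest(config, manifest, failed=stage)
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    _write_manifest(config, manifest)
    return manifest


def _write_manifest(config, manifest, failed: str | None = None):
    if failed:
        manifest = {**manifest, "failed_stage": failed}
    path = os.path.join(config.out_dir, "manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _bundle(config: PipelineConfig, state) -> StudyBundle:
    if "bundle" not in state:
        state["bundle"] = read_study_bundle(config.input_dir)
    return state["bundle"]


def _stage_simulate(config, state, register):
    bundle = generate_study(config.study_config())
    bdir = os.path.join(config.out_dir, "bundle")
    os.makedirs(bdir, exist_ok=True)
    write_study_bundle(bdir, bundle)
    state["bundle"] = bundle
    register("simulate", *(os.path.join(bdir, f) for f in
                           ("cohort.csv", "peaks_gc.csv", "peaks_lc.csv", "panel.yaml")))
    log.info("simulate: %d subjects, %d chemicals",
             len(bundle.cohort), bundle.truth.true_concentration.shape[1])


def _stage_quantify(config, state, register):
    bundle = _bundle(config, state)
    quant = quantify_study(bundle.peak_tables, bundle.panel,
                           noise_sd=bundle.truth.noise_floor)
    imputed = impute_below_loq(quant.matrix)
    state["quant"], state["matrix"] = quant, imputed
    adir = os.path.join(config.out_dir, "atlas")
    os.makedirs(adir, exist_ok=True)
    paths = []
    for name, df in (("concentrations.csv", imputed.values),
                     ("below_loq.csv", imputed.below_loq.astype(int)),
                     ("cell_batches.csv", imputed.batch)):
        p = os.path.join(adir, name)
        df.rename_axis("subject_id").to_csv(p)
        paths.append(p)
    p = os.path.join(adir, "calibration_report.csv")
    quant.fits_frame().to_csv(p, index=False)
    paths.append(p)
    register("quantify", *paths)


def _stage_qc(config, state, register):
    bundle = _bundle(config, state)
    quant = state["quant"]
    report = qc_mod.qc_metrics(quant.qc_concentrations)
    qdir = os.path.join(config.out_dir, "qc")
    os.makedirs(qdir, exist_ok=True)
    paths = []
    for name, df in (("precision.csv", report.precision),
                     ("recovery.csv", report.recovery),
                     ("summary.csv", report.summary),
                     ("curve_accuracy.csv", quant.accuracy)):
        p = os.path.join(qdir, name)
        df.to_csv(p, index=False)
        paths.append(p)
    # batch effects: raw QC areas vs IS-corrected quantified QC concentrations
    rows = []
    for platform, table in bundle.peak_tables.items():
        prec = (config.study.get("qc_precision_level_gc", 2.0) if platform == "GC"
                else config.study.get("qc_precision_level_lc", 10.0))
        qc_rows = table[(table["role"] == "qc")
                        & (table["nominal_conc_ng_ml"] == prec)]
        chems = [c.chemical_id for c in bundle.panel.by_platform(platform)]
        before = qc_rows[qc_rows["chemical_id"].isin(chems)].pivot_table(
            index="sample_id", columns="chemical_id", values="area")
        batches = qc_rows.drop_duplicates("sample_id").set_index("sample_id")["batch"]
        after_long = quant.qc_concentrations
        after = after_long[(after_long["platform"] == platform)
                           & (after_long["nominal"] == prec)].pivot_table(
            index="sample_id", columns="chemical_id", values="conc")
        common = before.index.intersection(after.index)
        if len(batches.loc[common].unique()) < 2:
            continue
        assess = qc_mod.batch_effect_assessment(
            before.loc[common], after.loc[common].clip(lower=1e-9),
            batches.loc[common])
        rows.append({"platform": platform,
                     "metric_before": assess["metric_before"],
                     "metric_after": assess["metric_after"]})
    be = pd.DataFrame(rows)
    p = os.path.join(qdir, "batch_effect.csv")
    be.to_csv(p, index=False)
    paths.append(p)
    state["qc_report"] = report
    register("qc", *paths)


def _stage_outcomes(config, state, register):
    bundle = _bundle(config, state)
    labels = out_mod.classify_outcomes(bundle.cohort)
    state["labels"] = labels
    odir = os.path.join(config.out_dir, "outcomes")
    os.makedirs(odir, exist_ok=True)
    p = os.path.join(odir, "labels.csv")
    out = labels.copy()
    for c in out.columns:
        if str(out[c].dtype) == "boolean":
            out[c] = out[c].map({True: 1, False: 0}).astype("Int64")
    out.to_csv(p, index=False)
    paths = [p]
    matched = {}
    for outcome in config.analysis_outcomes:
        m = out_mod.match_controls(bundle.cohort, labels, outcome,
                                   caliper=config.caliper)
        matched[outcome] = m
        p = os.path.join(odir, f"matched_{outcome}.csv")
        m.pairs().to_csv(p, index=False)
        paths.append(p)
    state["matched"] = matched
    register("outcomes", *paths)


def _stage_characterize(config, state, register):
    bundle = _bundle(config, state)
    matrix = state["matrix"]
    coh = bundle.cohort.set_index("subject_id")
    regions = coh["region"].reindex(matrix.values.index)
    cdir = os.path.join(config.out_dir, "characterization")
    os.makedirs(cdir, exist_ok=True)
    table = char_mod.concentration_table(matrix, regions)
    state["detection"] = char_mod.detection_frequency(matrix, regions)
    high = char_mod.select_high_frequency(state["detection"])
    state["high_frequency"] = high
    coh_m = coh.reindex(matrix.values.index)
    vp = char_mod.variance_partition(matrix.values, coh_m.reset_index(), EPI_FACTORS)
    ps = char_mod.partial_spearman(matrix.values, coh_m.reset_index(), "age",
                                   [f for f in EPI_FACTORS if f != "age"])
    scores, loadings, expl = char_mod.pca_scores(matrix.values)
    paths = []
    for name, df in (("concentration_table.csv", table.rename_axis("chemical_id")),
                     ("variance_partition.csv", vp),
                     ("partial_spearman_age.csv", ps),
                     ("pca_scores.csv", scores.rename_axis("subject_id").iloc[:, :5]),
                     ("pca_explained.csv", expl.rename("explained").to_frame())):
        p = os.path.join(cdir, name)
        df.to_csv(p)
        paths.append(p)
    register("characterize", *paths)


def _stage_associations(config, state, register):
    bundle = _bundle(config, state)
    matrix, labels = state["matrix"], state["labels"]
    high = state.get("high_frequency") or list(matrix.values.columns)
    results = []
    for outcome, m in state["matched"].items():
        for chem in matrix.values.columns:
            try:
                r = assoc_mod.fit_matched(m, matrix.values, bundle.cohort,
                                          labels, chem)
                r.low_frequency = chem not in high
                results.append(r)
            except ValueError as exc:
                log.warning("assoc %s/%s skipped: %s", chem, outcome, exc)
    adir = os.path.join(config.out_dir, "associations")
    os.makedirs(adir, exist_ok=True)
    p = os.path.join(adir, "single_exposure.csv")
    assoc_mod.results_frame(results).to_csv(p, index=False)
    state["assoc_results"] = results
    register("associations", p)


def _stage_mixtures(config, state, register):
    bundle = _bundle(config, state)
    matrix, labels = state["matrix"], state["labels"]
    high = state.get("high_frequency") or list(matrix.values.columns)
    # mixture cohort: subjects measured on both platforms, high-frequency panel
    measured = matrix.batch.notna()
    per_platform = {}
    for chem in matrix.values.columns:
        plat = bundle.panel.chemical(chem).platform
        per_platform.setdefault(plat, []).append(chem)
    both = pd.Series(True, index=matrix.values.index)
    for plat, chems in per_platform.items():
        both &= measured[chems].any(axis=1)
    chems = [c for c in high if matrix.values.loc[both, c].notna().all()]
    if len(chems) < 2:
        chems = [c for c in matrix.values.columns
                 if matrix.values.loc[both, c].notna().all()][:4]
    sub = np.log10(matrix.values.loc[both, chems])
    sub = (sub - sub.mean()) / sub.std().replace(0, 1.0)
    quant = mix_mod.quantize(sub)
    coh = bundle.cohort.set_index("subject_id").reindex(sub.index)
    from .design import build_covariate_design, standardize
    Z = standardize(build_covariate_design(coh.reset_index(),
                                           mix_mod.MIXTURE_COVARIATES))
    Z.index = sub.index
    mdir = os.path.join(config.out_dir, "mixtures")
    os.makedirs(mdir, exist_ok=True)
    rows, wrows, paths = [], [], []
    lab = labels.set_index("subject_id") if "subject_id" in labels else labels
    for outcome in config.analysis_outcomes:
        y = (lab[outcome].reindex(sub.index) == True).astype(float)  # noqa: E712
        wqs = mix_mod.fit_wqs(quant, y, Z, direction="positive",
                              n_boot=config.n_boot, split=config.wqs_split,
                              seed=config.seed, outcome_name=outcome)
        qg = mix_mod.fit_qgcomp(quant, y, Z, outcome_name=outcome)
        for r in (wqs, qg):
            rows.append({"outcome": outcome, "model": r.model,
                         "direction": r.direction, "beta": r.beta, "se": r.se,
                         "or": r.or_, "ci_low": r.ci_low, "ci_high": r.ci_high,
                         "ci_low_conventional": r.ci_low_conventional,
                         "ci_high_conventional": r.ci_high_conventional,
                         "p": r.p, "n_bootstrap": r.n_bootstrap,
                         "seed": config.seed})
            for chem, w in r.weights.items():
                wrows.append({"outcome": outcome, "model": r.model,
                              "chemical_id": chem, "weight": w})
    p = os.path.join(mdir, "mixture_results.csv")
    pd.DataFrame(rows).to_csv(p, index=False)
    paths.append(p)
    p = os.path.join(mdir, "mixture_weights.csv")
    pd.DataFrame(wrows).to_csv(p, index=False)
    paths.append(p)
    register("mixtures", *paths)


def _stage_risk(config, state, register):
    bundle = _bundle(config, state)
    matrix, labels = state["matrix"], state["labels"]
    guidance = pd.DataFrame(
        [{"chemical_id": c.chemical_id, "type": c.guidance_type,
          "value_ng_ml": c.guidance_value}
         for c in bundle.panel.chemicals if c.guidance_value is not None])
    rdir = os.path.join(config.out_dir, "risk")
    os.makedirs(rdir, exist_ok=True)
    paths = []
    if not guidance.empty:
        hq = risk_mod.hazard_quotients(matrix.values, guidance)
        p = os.path.join(rdir, "exceedance.csv")
        hq["exceedance_pct"].rename_axis("chemical_id").to_csv(p)
        paths.append(p)
    lab = labels.set_index("subject_id") if "subject_id" in labels else labels
    coh = bundle.cohort.set_index("subject_id")
    for outcome, m in state["matched"].items():
        ids = list(m.case_ids) + list(m.control_ids)
        y = (lab[outcome].reindex(ids) == True).astype(float)  # noqa: E712
        chem = matrix.values.columns[0]
        if state.get("assoc_results"):
            fine = [r for r in state["assoc_results"]
                    if r.outcome == outcome and np.isfinite(r.p)]
            if fine:
                chem = min(fine, key=lambda r: r.p).chemical
        curve = risk_mod.dose_risk_curve(
            matrix.values[chem].reindex(ids), y, coh.loc[ids],
            chemical=chem, outcome_name=outcome, n_knots=config.n_knots)
        p = os.path.join(rdir, f"dose_risk_{outcome}_{chem}.csv")
        curve.grid.to_csv(p, index=False)
        paths.append(p)
    register("risk", *paths)
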