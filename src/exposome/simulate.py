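"""Synthetic serum-biomonitoring study generator.

Emulates the statistical structure the downstream pipeline assumes:

* a cohort with nine epidemiological factors and nine clinical parameters
  whose marginals sit near the published cohort table;
* log-normal true exposure concentrations with region/age/sex structure
  (region dominating, age second);
* long-format instrument peak tables for two virtual platforms, with a
  full calibration ladder and interleaved QC spikes in every batch, and
  multiplicative per-batch drift shared between each analyte and its
  matched internal standard — the property IS correction exploits;
* chronic-disease outcomes generated through a logistic link on log10
  true concentration, realised by writing the corresponding clinical
  parameter above/below its diagnostic threshold.

Everything is a pure function of ``StudyConfig`` (including its seed); a
truth record is returned so recovery tests can compare against it.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .config import (
    CLINICAL_PARAMS,
    ConfigurationError,
    EDUCATION_LEVELS,
    MARITAL_STATUSES,
    Panel,
    SAMPLING_MONTHS,
    StudyConfig,
    default_panel,
)

PLATFORMS = ("GC", "LC")

# stage tags keep per-operation RNG streams independent but seed-determined
_STAGE = {"panel": 11, "cohort": 23, "exposures": 37, "peaks": 53, "outcomes": 71}


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([_STAGE[stage], seed]))


@dataclass
class SyntheticTruth:
    """Ground truth behind a synthetic study."""

    true_concentration: pd.DataFrame          # subject x chemical, ng/mL
    response_factor: pd.Series                # chemical -> area per ng/mL
    is_response: pd.Series                    # is_id -> area at constant spike
    is_assignment: pd.Series                  # chemical -> matched is_id
    batch_drift: dict                         # platform -> DataFrame batch x compound
    sample_batches: dict                      # platform -> Series sample_id -> batch
    noise_floor: pd.Series                    # chemical -> chromatographic noise sd (area)
    loq_target: pd.Series                     # chemical -> intended LOQ (ng/mL)
    detection_target: pd.Series               # chemical -> target detection fraction
    region_offsets: pd.DataFrame              # region x chemical, log10 offsets
    age_slopes: pd.Series                     # chemical -> log10 per year
    noise_cv: float = 0.05
    outcome_effects: dict = field(default_factory=dict)
    outcome_labels: pd.DataFrame | None = None  # injected outcome truth (subject x outcome)


@dataclass
class StudyBundle:
    cohort: pd.DataFrame
    peak_tables: dict
    panel: Panel
    truth: SyntheticTruth
    config: StudyConfig


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def generate_cohort(config: StudyConfig) -> pd.DataFrame:
    """Draw a cohort table with marginals near the published study population."""
    config.validate()
    rng = _rng(config.seed, "cohort")
    n = config.n_subjects

    sex = np.where(rng.random(n) < 2607 / 5696, "M", "F")
    age = np.clip(np.round(rng.normal(51, 17, n)), 5, 85).astype(int)
    regions = list(config.regions)
    region = np.asarray(regions)[rng.integers(0, len(regions), n)]
    # sampling was conducted region by region: month is a region block with
    # a small spill into the following month
    base_month = {r: i % len(SAMPLING_MONTHS) for i, r in enumerate(regions)}
    spill = (rng.random(n) < 0.15).astype(int)
    month_idx = np.array([base_month[r] for r in region])
    month = np.asarray(SAMPLING_MONTHS)[(month_idx + spill) % len(SAMPLING_MONTHS)]
    edu_probs = np.array([2108, 1828, 1236, 524]) / 5696
    education = np.asarray(EDUCATION_LEVELS)[rng.choice(4, n, p=edu_probs)]
    income = rng.lognormal(mean=9.341, sigma=1.155, size=n).round(0)
    marital = np.asarray(MARITAL_STATUSES)[
        rng.choice(3, n, p=np.array([4853, 468, 375]) / 5696)]
    smoking = np.where(rng.random(n) < np.where(sex == "M", 0.49, 0.04), "yes", "no")
    drinking = np.where(rng.random(n) < np.where(sex == "M", 0.55, 0.04), "yes", "no")

    male = sex == "M"
    uric = np.where(male, rng.normal(323, 85, n), rng.normal(265, 74, n))
    clin = {
        "uric_acid": np.clip(uric, 80, None).round(1),
        "hba1c": np.clip(rng.normal(5.7, 0.9, n), 3.5, None).round(2),
        "ldl_c": np.clip(rng.normal(3.1, 0.9, n), 0.5, None).round(2),
        "triglycerides": rng.lognormal(0.130, 0.642, n).round(2),
        "total_cholesterol": np.clip(rng.normal(4.9, 1.1, n), 1.5, None).round(2),
        "sbp": np.clip(rng.normal(127, 20, n), 70, None).round(0),
        "dbp": np.clip(rng.normal(81, 12, n), 40, None).round(0),
        "waistline": np.clip(np.where(male, rng.normal(85, 12, n), rng.normal(82, 11, n)),
                             50, None).round(1),
        "bmi": np.clip(rng.normal(23.9, 3.8, n), 13, None).round(1),
    }
    cohort = pd.DataFrame({
        "subject_id": [f"S{i + 1:05d}" for i in range(n)],
        "sex": sex, "age": age, "region": region, "sampling_month": month,
        "education": education, "income": income, "marital_status": marital,
        "smoking": smoking, "drinking": drinking, **clin,
    })
    if config.missing_rate > 0:
        mask = rng.random((n, len(CLINICAL_PARAMS))) < config.missing_rate
        for j, p in enumerate(CLINICAL_PARAMS):
            cohort.loc[mask[:, j], p] = np.nan
    return cohort


# ---------------------------------------------------------------------------
# exposures
# ---------------------------------------------------------------------------

def _platform_loq_targets(panel: Panel) -> pd.Series:
    """Intended LOQ per chemical: a low rung of its platform's ladder, cycled."""
    from .config import CALIB_LEVELS_GC, CALIB_LEVELS_LC
    rungs = {"GC": CALIB_LEVELS_GC[2:5], "LC": CALIB_LEVELS_LC[3:6]}
    out = {}
    counters = {"GC": 0, "LC": 0}
    for chem in panel.chemicals:
        r = rungs[chem.platform]
        out[chem.chemical_id] = r[counters[chem.platform] % len(r)]
        counters[chem.platform] += 1
    return pd.Series(out, name="loq_target")


def generate_exposures(
    cohort: pd.DataFrame,
    config: StudyConfig,
    panel: Panel | None = None,
    *,
    region_offsets: pd.DataFrame | None = None,
    age_slopes: pd.Series | None = None,
    subject_sd: float | None = None,
) -> SyntheticTruth:
    """Draw true concentrations and the full instrument ground truth.

    log10 C = baseline + region offset + age slope * age + subject noise,
    with the baseline solved per chemical so the fraction of subjects above
    the chemical's intended LOQ matches its configured detection target.
    Keyword overrides pin the structural effects for tests.
    """
    if cohort.empty:
        raise ConfigurationError("cohort is empty")
    rng = _rng(config.seed, "exposures")
    if panel is None:
        panel = default_panel(config, _rng(config.seed, "panel"))
    chems = [c.chemical_id for c in panel.chemicals]
    regions = list(config.regions)
    n = len(cohort)
    sd_subj = config.subject_sd_log10 if subject_sd is None else subject_sd

    if region_offsets is None:
        if config.region_offsets is not None:
            off = np.tile(
                np.array([config.region_offsets[r] for r in regions])[:, None],
                (1, len(chems)))
        else:
            off = rng.normal(0.0, config.region_sd_log10, size=(len(regions), len(chems)))
            off -= off.mean(axis=0, keepdims=True)
        region_offsets = pd.DataFrame(off, index=regions, columns=chems)
    if age_slopes is None:
        age_slopes = pd.Series(
            rng.normal(config.age_slope_mean, config.age_slope_sd, len(chems)),
            index=chems, name="age_slope")

    loq_target = _platform_loq_targets(panel)
    targets = list(config.detection_targets)
    detection_target = pd.Series(
        [targets[j % len(targets)] for j in range(len(chems))], index=chems,
        name="detection_target")

    age = cohort["age"].to_numpy(float)
    reg_of_subj = region_offsets.reindex(cohort["region"]).to_numpy()  # n x p
    struct = reg_of_subj + np.outer(age, age_slopes.to_numpy())        # n x p
    mu_struct = struct.mean(axis=0)
    sd_struct = struct.std(axis=0)
    sigma_total = np.sqrt(sd_subj ** 2 + sd_struct ** 2)
    from scipy.stats import norm
    z = norm.ppf(detection_target.to_numpy())
    # P(log10 C >= log10 LOQ) = target
    baseline = np.log10(loq_target.reindex(chems).to_numpy()) + z * sigma_total - mu_struct

    log10c = baseline + struct + rng.normal(0.0, sd_subj, size=(n, len(chems)))
    conc = pd.DataFrame(10.0 ** log10c, index=cohort["subject_id"].to_numpy(),
                        columns=chems).rename_axis("subject_id")

    response_factor = pd.Series(
        10.0 ** rng.uniform(3.5, 4.5, len(chems)), index=chems, name="response_factor")
    # noise floor set so S/N at the intended LOQ rung is ~14 (next rung down
    # on either ladder is >= 2x lower, i.e. S/N <= 7): robust to modest drift
    noise_floor = response_factor * loq_target.reindex(chems) / 14.0
    is_ids = [s.is_id for s in panel.internal_standards]
    is_response = pd.Series(10.0 ** rng.uniform(4.5, 5.5, len(is_ids)),
                            index=is_ids, name="is_response")

    # true matched IS: nearest retention time on the chemical's platform
    assignment = {}
    for chem in panel.chemicals:
        cands = [panel.internal_standard(i) for i in chem.candidate_is]
        if not cands:
            assignment[chem.chemical_id] = "external"
            continue
        best = min(cands, key=lambda s: (abs(s.rt - chem.rt), s.rt))
        assignment[chem.chemical_id] = best.is_id
    is_assignment = pd.Series(assignment, name="is_id")

    # per-batch multiplicative drift, drawn per IS and copied to its analytes
    batch_drift: dict[str, pd.DataFrame] = {}
    sample_batches: dict[str, pd.Series] = {}
    subject_ids = cohort["subject_id"].tolist()
    for platform in PLATFORMS:
        layout = config.batch_layout_gc if platform == "GC" else config.batch_layout_lc
        samples = config.platform_samples(platform, subject_ids)
        n_batches = layout.n_batches(len(samples))
        batches = [f"{platform}B{k + 1:02d}" for k in range(n_batches)]
        plat_is = [s.is_id for s in panel.internal_standards if s.platform == platform]
        drift_is = pd.DataFrame(
            10.0 ** rng.normal(0.0, config.drift_sd_log10, size=(n_batches, len(plat_is))),
            index=batches, columns=plat_is)
        plat_chems = [c.chemical_id for c in panel.by_platform(platform)]
        cols = {}
        for c in plat_chems:
            isid = is_assignment[c]
            cols[c] = drift_is[isid] if isid in drift_is else pd.Series(1.0, index=batches)
        drift = pd.concat({**cols, **{i: drift_is[i] for i in plat_is}}, axis=1)
        batch_drift[platform] = drift
        lab = np.repeat(batches, layout.real_per_batch)[: len(samples)]
        sample_batches[platform] = pd.Series(lab, index=samples, name="batch")

    return SyntheticTruth(
        true_concentration=conc,
        response_factor=response_factor,
        is_response=is_response,
        is_assignment=is_assignment,
        batch_drift=batch_drift,
        sample_batches=sample_batches,
        noise_floor=noise_floor.rename("noise_floor"),
        loq_target=loq_target.reindex(chems),
        detection_target=detection_target,
        region_offsets=region_offsets,
        age_slopes=age_slopes,
        noise_cv=config.noise_cv,
        outcome_effects=dict(config.outcome_effects),
    )


# ---------------------------------------------------------------------------
# peak tables
# ---------------------------------------------------------------------------

def _noisy(base: np.ndarray, cv: float, rng: np.random.Generator) -> np.ndarray:
    """area = base * (1 + eps), eps ~ N(0, cv) truncated at -0.99."""
    if cv == 0:
        return base.copy()
    eps = np.clip(rng.normal(0.0, cv, size=base.shape), -0.99, None)
    return base * (1.0 + eps)


def generate_peak_tables(truth: SyntheticTruth, config: StudyConfig,
                         panel: Panel) -> dict:
    """Long-format peak tables per platform.

    Each batch holds a full calibration ladder, its QC spikes (one per
    accuracy level, the remainder at the precision level) and its study
    samples.  Analyte rows carry the matched IS id/area; internal standards
    are additionally emitted as their own rows so a data-driven IS
    selection can evaluate every candidate.
    """
    rng = _rng(config.seed, "peaks")
    tables = {}
    for platform in PLATFORMS:
        layout = config.batch_layout_gc if platform == "GC" else config.batch_layout_lc
        levels = (config.calib_levels_gc if platform == "GC" else config.calib_levels_lc)
        acc = list(config.qc_accuracy_levels_gc if platform == "GC"
                   else config.qc_accuracy_levels_lc)
        prec = (config.qc_precision_level_gc if platform == "GC"
                else config.qc_precision_level_lc)
        chems = [c.chemical_id for c in panel.by_platform(platform)]
        if not chems:
            continue
        for c in chems:
            if c not in truth.response_factor.index:
                raise ConfigurationError(f"chemical {c} has no response factor")
        plat_is = [s.is_id for s in panel.internal_standards if s.platform == platform]
        drift = truth.batch_drift[platform]
        batches = list(drift.index)
        sb = truth.sample_batches[platform]

        sample_ids: list[str] = []
        roles: list[str] = []
        batch_of: list[str] = []
        nominal: list[float] = []
        for b in batches:
            for i, lv in enumerate(levels):
                sample_ids.append(f"{b}_CAL{i:02d}")
                roles.append("calibrator")
                batch_of.append(b)
                nominal.append(lv)
            qc_levels = acc + [prec] * max(0, layout.qc_per_batch - len(acc))
            for i, lv in enumerate(qc_levels[: layout.qc_per_batch]):
                sample_ids.append(f"{b}_QC{i:02d}")
                roles.append("qc")
                batch_of.append(b)
                nominal.append(lv)
            for s in sb.index[sb == b]:
                sample_ids.append(s)
                roles.append("study")
                batch_of.append(b)
                nominal.append(np.nan)

        n_s = len(sample_ids)
        roles_a = np.asarray(roles)
        nominal_a = np.asarray(nominal)
        # concentration matrix: calibrator/qc spiked at nominal for every
        # analyte; study samples at their true concentration
        conc = np.tile(nominal_a[:, None], (1, len(chems)))
        study_mask = roles_a == "study"
        conc[study_mask] = truth.true_concentration.loc[
            np.asarray(sample_ids, dtype=object)[study_mask], chems].to_numpy()

        rf = truth.response_factor.reindex(chems).to_numpy()
        drift_chem = drift.loc[batch_of, chems].to_numpy()
        base_area = rf[None, :] * conc * drift_chem
        area = _noisy(base_area, truth.noise_cv, rng)

        isr = truth.is_response.reindex(plat_is).to_numpy()
        drift_is = drift.loc[batch_of, plat_is].to_numpy()
        is_area_all = _noisy(isr[None, :] * drift_is, truth.noise_cv, rng)
        is_area_df = pd.DataFrame(is_area_all, columns=plat_is)

        frames = []
        assign = truth.is_assignment.reindex(chems)
        for j, c in enumerate(chems):
            isid = assign[c]
            frames.append(pd.DataFrame({
                "sample_id": sample_ids, "role": roles, "batch": batch_of,
                "platform": platform, "chemical_id": c, "area": area[:, j],
                "is_id": isid if isid in plat_is else "",
                "is_area": is_area_df[isid].to_numpy() if isid in plat_is else np.nan,
                "nominal_conc_ng_ml": nominal_a,
            }))
        for i, s_id in enumerate(plat_is):
            frames.append(pd.DataFrame({
                "sample_id": sample_ids, "role": roles, "batch": batch_of,
                "platform": platform, "chemical_id": s_id,
                "area": is_area_all[:, i], "is_id": "", "is_area": np.nan,
                "nominal_conc_ng_ml": np.nan,
            }))
        tables[platform] = pd.concat(frames, ignore_index=True)
    return tables


# ---------------------------------------------------------------------------
# outcome injection
# ---------------------------------------------------------------------------

# outcome -> (clinical parameter, threshold by sex, strict inequality?)
_INJECTABLE = {
    "hyperuricemia": ("uric_acid", {"M": 420.0, "F": 360.0}, False),
    "diabetes": ("hba1c", {"M": 6.5, "F": 6.5}, False),
    "hyper_ldl_c": ("ldl_c", {"M": 3.4, "F": 3.4}, False),
    "hypertriglyceridemia": ("triglycerides", {"M": 2.3, "F": 2.3}, False),
    "hypercholesterolemia": ("total_cholesterol", {"M": 6.2, "F": 6.2}, False),
    "high_sbp": ("sbp", {"M": 140.0, "F": 140.0}, False),
    "high_dbp": ("dbp", {"M": 90.0, "F": 90.0}, False),
    "abdominal_obesity": ("waistline", {"M": 90.0, "F": 85.0}, False),
    "obesity": ("bmi", {"M": 28.0, "F": 28.0}, True),
}


def inject_outcomes(cohort: pd.DataFrame, truth: SyntheticTruth,
                    config: StudyConfig) -> pd.DataFrame:
    """Embed exposure-disease effects by rewriting clinical parameters.

    For each configured outcome, the disease indicator is drawn from a
    logistic model on log10 true concentration (log-OR per log10 ng/mL as
    configured) plus a mild age effect; the outcome's clinical parameter is
    then rewritten just above/below its diagnostic threshold so the outcome
    classifier reproduces the drawn labels exactly.  Returns a new cohort;
    the drawn labels are recorded on ``truth.outcome_labels``.
    """
    from scipy.special import expit

    rng = _rng(config.seed, "outcomes")
    cohort = cohort.copy()
    labels = {}
    for outcome, effects in config.outcome_effects.items():
        if outcome not in _INJECTABLE:
            raise ConfigurationError(
                f"outcome {outcome!r} is not injectable (composite or unknown)")
        param, thr_by_sex, strict = _INJECTABLE[outcome]
        effects = dict(effects)
        intercept = effects.pop("_intercept", -1.2)
        age_beta = effects.pop("_age", 0.02)
        lin = np.full(len(cohort), intercept, float)
        lin += age_beta * (cohort["age"].to_numpy(float) - 51.0)
        for chem, beta in effects.items():
            x = np.log10(truth.true_concentration.loc[
                cohort["subject_id"].to_numpy(), chem].to_numpy())
            lin += beta * (x - x.mean())
        y = rng.random(len(cohort)) < expit(lin)
        thr = cohort["sex"].map(thr_by_sex).to_numpy(float)
        above = thr * (1.0 + (0.005 if strict else 0.0) + np.abs(rng.normal(0.0, 0.12, len(cohort))))
        below = np.clip(thr * (1.0 - 0.02 - np.abs(rng.normal(0.0, 0.12, len(cohort)))),
                        0.05 * thr, None)
        cohort[param] = np.round(np.where(y, above, below), 3)
        labels[outcome] = y
    truth.outcome_labels = pd.DataFrame(labels, index=cohort["subject_id"].to_numpy())
    return cohort


# ---------------------------------------------------------------------------
# bundle assembly and I/O
# ---------------------------------------------------------------------------

def generate_study(config: StudyConfig, panel: Panel | None = None) -> StudyBundle:
    """Cohort -> exposures -> outcome injection -> peak tables, one call."""
    config.validate()
    if panel is None:
        panel = default_panel(config, _rng(config.seed, "panel"))
    cohort = generate_cohort(config)
    truth = generate_exposures(cohort, config, panel)
    if config.outcome_effects:
        cohort = inject_outcomes(cohort, truth, config)
    peaks = generate_peak_tables(truth, config, panel)
    return StudyBundle(cohort=cohort, peak_tables=peaks, panel=panel,
                       truth=truth, config=config)


def write_study_bundle(outdir, bundle: StudyBundle) -> None:
    """Write the bundle as plain CSV/YAML under an existing directory."""
    outdir = os.fspath(outdir)
    if not os.path.isdir(outdir):
        raise IOError(f"output directory does not exist: {outdir}")
    bundle.cohort.to_csv(os.path.join(outdir, "cohort.csv"), index=False)
    for platform, table in bundle.peak_tables.items():
        table.to_csv(os.path.join(outdir, f"peaks_{platform.lower()}.csv"), index=False)
    bundle.panel.to_yaml(os.path.join(outdir, "panel.yaml"))

    t = bundle.truth
    tdir = os.path.join(outdir, "truth")
    os.makedirs(tdir, exist_ok=True)
    t.true_concentration.rename_axis("subject_id").to_csv(
        os.path.join(tdir, "true_concentration.csv"))
    params = pd.concat(
        [t.response_factor, t.noise_floor, t.loq_target.rename("loq_target"),
         t.detection_target, t.age_slopes.rename("age_slope"),
         t.is_assignment.rename("is_id")], axis=1)
    params.rename_axis("chemical_id").to_csv(os.path.join(tdir, "chemical_params.csv"))
    t.is_response.rename_axis("is_id").to_csv(os.path.join(tdir, "is_response.csv"))
    t.region_offsets.rename_axis("region").to_csv(os.path.join(tdir, "region_offsets.csv"))
    for platform in t.batch_drift:
        t.batch_drift[platform].rename_axis("batch").to_csv(
            os.path.join(tdir, f"batch_drift_{platform.lower()}.csv"))
        t.sample_batches[platform].rename_axis("sample_id").to_csv(
            os.path.join(tdir, f"sample_batches_{platform.lower()}.csv"))
    if t.outcome_labels is not None:
        t.outcome_labels.rename_axis("subject_id").to_csv(
            os.path.join(tdir, "outcome_labels.csv"))
    with open(os.path.join(tdir, "meta.yaml"), "w") as fh:
        yaml.safe_dump({"noise_cv": float(t.noise_cv),
                        "outcome_effects": {k: dict(v) for k, v in t.outcome_effects.items()},
                        "seed": int(bundle.config.seed)}, fh)


def read_study_bundle(indir, config: StudyConfig | None = None) -> StudyBundle:
    indir = os.fspath(indir)
    cohort = pd.read_csv(os.path.join(indir, "cohort.csv"))
    panel = Panel.from_yaml(os.path.join(indir, "panel.yaml"))
    peaks = {}
    for platform in PLATFORMS:
        path = os.path.join(indir, f"peaks_{platform.lower()}.csv")
        if os.path.exists(path):
            peaks[platform] = pd.read_csv(
                path, dtype={"is_id": str}, keep_default_na=True).fillna({"is_id": ""})
    tdir = os.path.join(indir, "truth")
    conc = pd.read_csv(os.path.join(tdir, "true_concentration.csv"),
                       index_col="subject_id")
    params = pd.read_csv(os.path.join(tdir, "chemical_params.csv"),
                         index_col="chemical_id")
    is_response = pd.read_csv(os.path.join(tdir, "is_response.csv"),
                              index_col="is_id").iloc[:, 0]
    region_offsets = pd.read_csv(os.path.join(tdir, "region_offsets.csv"),
                                 index_col="region")
    batch_drift, sample_batches = {}, {}
    for platform in PLATFORMS:
        p = os.path.join(tdir, f"batch_drift_{platform.lower()}.csv")
        if os.path.exists(p):
            batch_drift[platform] = pd.read_csv(p, index_col="batch")
            sample_batches[platform] = pd.read_csv(
                os.path.join(tdir, f"sample_batches_{platform.lower()}.csv"),
                index_col="sample_id").iloc[:, 0]
    with open(os.path.join(tdir, "meta.yaml")) as fh:
        meta = yaml.safe_load(fh)
    ol_path = os.path.join(tdir, "outcome_labels.csv")
    outcome_labels = (pd.read_csv(ol_path, index_col="subject_id")
                      if os.path.exists(ol_path) else None)
    truth = SyntheticTruth(
        true_concentration=conc,
        response_factor=params["response_factor"],
        is_response=is_response,
        is_assignment=params["is_id"],
        batch_drift=batch_drift,
        sample_batches=sample_batches,
        noise_floor=params["noise_floor"],
        loq_target=params["loq_target"],
        detection_target=params["detection_target"],
        region_offsets=region_offsets,
        age_slopes=params["age_slope"],
        noise_cv=meta["noise_cv"],
        outcome_effects=meta.get("outcome_effects", {}),
        outcome_labels=outcome_labels,
    )
    cfg = config or StudyConfig(n_subjects=len(cohort), seed=meta.get("seed", 0))
    return StudyBundle(cohort=cohort, peak_tables=peaks, panel=panel,
                       truth=truth, config=cfg)
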