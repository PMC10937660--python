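"""Study configuration and chemical panel definitions.

The study design mirrors a large serum biomonitoring campaign run on two
targeted MS platforms ("GC" and "LC").  Each platform analyses samples in
instrument batches; every batch opens with a matrix-matched calibration
ladder and interleaves spiked QC serum among the study samples.  The panel
maps every analyte to its platform, chemical category, retention time,
candidate isotope-labelled internal standards, and (when available) a
health-based guidance value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import yaml

# The nine epidemiological factors recorded per subject.
EPI_FACTORS = (
    "sex",
    "age",
    "region",
    "sampling_month",
    "education",
    "income",
    "marital_status",
    "smoking",
    "drinking",
)

# The nine clinical parameters that define the chronic-disease outcomes.
CLINICAL_PARAMS = (
    "uric_acid",
    "hba1c",
    "ldl_c",
    "triglycerides",
    "total_cholesterol",
    "sbp",
    "dbp",
    "waistline",
    "bmi",
)

SAMPLING_MONTHS = ("Aug", "Sep", "Oct", "Nov")
EDUCATION_LEVELS = ("primary", "junior_high", "high_school", "university")
MARITAL_STATUSES = ("married", "unmarried", "other")

# Matrix-matched calibration ladders (ng/mL) per platform.
CALIB_LEVELS_GC = (0.0, 0.02, 0.05, 0.1, 0.2, 0.5, 1.0, 2.0, 5.0, 10.0, 20.0, 50.0, 100.0)
CALIB_LEVELS_LC = (
    0.0, 0.001, 0.0025, 0.005, 0.01, 0.025, 0.05, 0.1, 0.25, 0.5,
    1.0, 2.5, 5.0, 10.0, 25.0, 50.0, 100.0, 200.0,
)

CATEGORIES = (
    "OCP", "OPP", "herbicide", "fungicide", "PAH", "PCB", "PFAS",
    "phthalate", "bisphenol", "food_additive", "veterinary_drug",
)


class ConfigurationError(ValueError):
    """Raised when a study or panel configuration violates its invariants."""


@dataclass(frozen=True)
class BatchLayout:
    """Instrument batch composition: study samples and QC injections per batch."""

    real_per_batch: int
    qc_per_batch: int

    def n_batches(self, n_samples: int) -> int:
        return max(1, math.ceil(n_samples / self.real_per_batch))


@dataclass
class StudyConfig:
    """Everything needed to generate a synthetic study deterministically.

    The defaults encode the campaign design: batch layouts of 158 study
    samples + 21 QCs (GC) and 264 + 24 (LC), the printed calibration
    ladders, QC precision spikes at 2 ng/mL (GC) and 10 ng/mL (LC) with
    accuracy spikes at 2/5/20 and 1/10/100 ng/mL, and cohort marginals
    drawn near the published cohort table (n = 5696, age 51 +/- 17 y, ...).
    """

    n_subjects: int = 800
    n_chemicals_gc: int = 12
    n_chemicals_lc: int = 8
    regions: Sequence[str] = ("North", "South", "East", "West")
    batch_layout_gc: BatchLayout = field(default_factory=lambda: BatchLayout(158, 21))
    batch_layout_lc: BatchLayout = field(default_factory=lambda: BatchLayout(264, 24))
    calib_levels_gc: Sequence[float] = CALIB_LEVELS_GC
    calib_levels_lc: Sequence[float] = CALIB_LEVELS_LC
    qc_precision_level_gc: float = 2.0
    qc_precision_level_lc: float = 10.0
    qc_accuracy_levels_gc: Sequence[float] = (2.0, 5.0, 20.0)
    qc_accuracy_levels_lc: Sequence[float] = (1.0, 10.0, 100.0)
    #: subjects measured per platform (defaults to all); the overlap of the
    #: two platform sample lists forms the mixture-analysis cohort.
    n_gc_samples: int | None = None
    n_lc_samples: int | None = None

    # --- exposure structure -------------------------------------------------
    #: per-chemical subject-level spread of log10 concentration
    subject_sd_log10: float = 0.4
    #: spread of region offsets on the log10 scale (region is the dominant
    #: exposure determinant, followed by age)
    region_sd_log10: float = 0.35
    age_slope_mean: float = 0.004
    age_slope_sd: float = 0.003
    #: detection-frequency targets cycled across the panel so some chemicals
    #: sit mostly below the LOQ
    detection_targets: Sequence[float] = (0.98, 0.90, 0.75, 0.55, 0.35, 0.20)
    #: explicit per-region log10 offsets (overrides the random draw)
    region_offsets: Mapping[str, float] | None = None

    # --- instrument model ---------------------------------------------------
    #: multiplicative area noise, CV parameterisation (RSD-style)
    noise_cv: float = 0.05
    #: sd of log10 batch drift shared between an analyte and its matched IS
    drift_sd_log10: float = 0.10

    # --- cohort -------------------------------------------------------------
    missing_rate: float = 0.0
    #: outcome -> {chemical_id: log-OR per log10(ng/mL)}; also accepts the
    #: pseudo-key "_intercept" controlling prevalence
    outcome_effects: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_subjects": self.n_subjects,
            "n_chemicals_gc": self.n_chemicals_gc,
            "n_chemicals_lc": self.n_chemicals_lc,
        }
        for name, v in counts.items():
            if not isinstance(v, (int,)) or v <= 0:
                raise ConfigurationError(f"{name} must be a positive integer, got {v!r}")
        if not self.regions:
            raise ConfigurationError("at least one region is required")
        for name, ladder in (("calib_levels_gc", self.calib_levels_gc),
                             ("calib_levels_lc", self.calib_levels_lc)):
            lad = list(ladder)
            if lad[0] != 0.0:
                raise ConfigurationError(f"{name} must start at 0")
            if any(b <= a for a, b in zip(lad, lad[1:])):
                raise ConfigurationError(f"{name} must be strictly increasing")
        for layout in (self.batch_layout_gc, self.batch_layout_lc):
            if layout.real_per_batch <= 0 or layout.qc_per_batch <= 0:
                raise ConfigurationError("batch layout counts must be positive")
        for attr in ("n_gc_samples", "n_lc_samples"):
            v = getattr(self, attr)
            if v is not None and not (0 < v <= self.n_subjects):
                raise ConfigurationError(f"{attr} must be in (0, n_subjects]")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigurationError("missing_rate must be in [0, 1)")
        if self.noise_cv < 0:
            raise ConfigurationError("noise_cv must be non-negative")

    def platform_samples(self, platform: str, subject_ids: Sequence[str]) -> list[str]:
        """Subject ids measured on a platform.

        GC takes the first ``n_gc_samples`` subjects and LC the last
        ``n_lc_samples`` so the two lists overlap (the common samples used
        for mixture modelling) without coinciding when the counts differ.
        """
        ids = list(subject_ids)
        if platform == "GC":
            n = self.n_gc_samples or len(ids)
            return ids[:n]
        if platform == "LC":
            n = self.n_lc_samples or len(ids)
            return ids[len(ids) - n:]
        raise ConfigurationError(f"unknown platform {platform!r}")


@dataclass(frozen=True)
class ChemicalSpec:
    chemical_id: str
    platform: str            # "GC" | "LC"
    category: str
    rt: float                # retention time, minutes
    candidate_is: tuple[str, ...]
    guidance_value: float | None = None   # ng/mL serum-equivalent
    guidance_type: str | None = None      # RfD | BE | HBM-II | BGV


@dataclass(frozen=True)
class InternalStandardSpec:
    is_id: str
    platform: str
    rt: float


@dataclass
class Panel:
    """The chemical panel: analytes plus the isotope-labelled IS pool."""

    chemicals: list[ChemicalSpec]
    internal_standards: list[InternalStandardSpec]

    def by_platform(self, platform: str) -> list[ChemicalSpec]:
        return [c for c in self.chemicals if c.platform == platform]

    def is_by_platform(self, platform: str) -> list[InternalStandardSpec]:
        return [s for s in self.internal_standards if s.platform == platform]

    def chemical(self, chemical_id: str) -> ChemicalSpec:
        for c in self.chemicals:
            if c.chemical_id == chemical_id:
                return c
        raise KeyError(chemical_id)

    def internal_standard(self, is_id: str) -> InternalStandardSpec:
        for s in self.internal_standards:
            if s.is_id == is_id:
                return s
        raise KeyError(is_id)

    # -- serialisation -------------------------------------------------------
    def to_yaml(self, path) -> None:
        payload = {
            "chemicals": [asdict(c) for c in self.chemicals],
            "internal_standards": [asdict(s) for s in self.internal_standards],
        }
        for entry in payload["chemicals"]:
            entry["candidate_is"] = list(entry["candidate_is"])
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "Panel":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        chems = [
            ChemicalSpec(
                chemical_id=d["chemical_id"],
                platform=d["platform"],
                category=d["category"],
                rt=float(d["rt"]),
                candidate_is=tuple(d["candidate_is"]),
                guidance_value=d.get("guidance_value"),
                guidance_type=d.get("guidance_type"),
            )
            for d in payload["chemicals"]
        ]
        standards = [
            InternalStandardSpec(is_id=d["is_id"], platform=d["platform"], rt=float(d["rt"]))
            for d in payload["internal_standards"]
        ]
        return cls(chemicals=chems, internal_standards=standards)


def default_panel(config: StudyConfig, rng) -> Panel:
    """Build a synthetic panel matching the configured panel sizes.

    One internal standard is provisioned per ~4 analytes on each platform.
    GC analytes list every platform IS as candidate (the static
    nearest-retention-time rule picks one); LC analytes likewise (the
    min-RSD rule picks one from QC data).  A subset of chemicals carries a
    guidance value so hazard quotients are computable.
    """
    chems: list[ChemicalSpec] = []
    standards: list[InternalStandardSpec] = []
    guidance_types = ("HBM-II", "BE", "BGV", "RfD")
    for platform, n_chem, rt_span in (("GC", config.n_chemicals_gc, (6.0, 40.0)),
                                      ("LC", config.n_chemicals_lc, (0.5, 16.0))):
        n_is = max(2, math.ceil(n_chem / 4))
        rts_is = rng.uniform(rt_span[0], rt_span[1], size=n_is)
        for k in range(n_is):
            standards.append(InternalStandardSpec(
                is_id=f"IS_{platform}{k + 1:02d}", platform=platform, rt=float(rts_is[k])))
        cand = tuple(s.is_id for s in standards if s.platform == platform)
        rts = rng.uniform(rt_span[0], rt_span[1], size=n_chem)
        for j in range(n_chem):
            has_guidance = j % 3 == 0
            chems.append(ChemicalSpec(
                chemical_id=f"{platform}_{j + 1:03d}",
                platform=platform,
                category=CATEGORIES[(j + (0 if platform == "GC" else 5)) % len(CATEGORIES)],
                rt=float(rts[j]),
                candidate_is=cand,
                guidance_value=float(rng.uniform(1.0, 50.0)) if has_guidance else None,
                guidance_type=guidance_types[j % 4] if has_guidance else None,
            ))
    return Panel(chemicals=chems, internal_standards=standards)
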