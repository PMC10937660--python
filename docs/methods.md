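# Methods

This note records the models, parameter choices, numerical conventions,
and known limitations of the `serum-exposome` package. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## 1. Synthetic study generator

The generator (`exposome.simulate`) is first-class, tested code: it
defines the study conditions every downstream module is validated
against.

**Cohort.** One row per subject with nine epidemiological factors and
nine clinical parameters. Marginals are fixed near a large Chinese
chronic-disease cohort: P(male) = 2607/5696, age ~ N(51, 17²) clipped to
[5, 85] years, education probabilities (0.37, 0.32, 0.22, 0.09), income
log-normal with mean ≈ 22 200 RMB/yr and SD ≈ 37 000 (µ = 9.341,
σ = 1.155 on the log scale), smoking/drinking strongly male-skewed
(≈ 49%/55% in men vs 4% in women), and clinical parameters at the
published means ± SDs (e.g. BMI 23.9 ± 3.8 kg/m², SBP 127 ± 20 mmHg,
uric acid sex-specific 323 ± 85 / 265 ± 74 µmol/L). Sampling month is
assigned as a per-region block (sampling campaigns run region by region)
with a 15% spill into the following month, so the region–month
confounding the characterisation module must cope with is reproducible.
A `missing_rate` option introduces missing clinical values; the default
is complete data.

**Exposures.** Per chemical *j* and subject *i*:

log10 C_ij = baseline_j + region_offset_j(r_i) + slope_j·age_i + ε_ij,
ε ~ N(0, σ_subj²)

with σ_subj = 0.4 log10 units, region offsets N(0, 0.35²) centered
across regions (region is the dominant structured effect), and age
slopes N(0.004, 0.003²) per year (age second). The baseline is solved
per chemical so that P(C ≥ LOQ target) equals a configured detection
target; targets cycle through (0.98, 0.90, 0.75, 0.55, 0.35, 0.20) so
part of the panel is mostly censored, as in real campaigns. All effects
are overridable per test.

**Instrument model.** Analyte area = RF·C·drift·(1 + ε) with
multiplicative Gaussian noise (CV parameterisation, truncated at −0.99
to keep areas positive — it maps directly onto RSD-style QC metrics;
default CV 5%). Batch drift is log-normal (σ = 0.10 log10 by default),
drawn **per internal standard per batch and copied to the analytes
assigned to that standard** — the drift-sharing property that IS
correction exploits, and the invariant the property tests assert.
The chromatographic noise floor is RF·LOQ_target/14, placing S/N ≈ 14 at
the intended LOQ rung and ≤ 7 one rung below, so the S/N > 10 rule lands
on the intended ladder level under modest drift.

**Batches.** Each platform batch holds a full calibration ladder
(GC: 0, 0.02, …, 100 ng/mL, 13 levels; LC: 0, 0.001, …, 200 ng/mL,
18 levels), its QC spikes (one at each accuracy level — GC 2/5/20,
LC 1/10/100 ng/mL — and the remainder at the precision level, 2 ng/mL GC
and 10 ng/mL LC), and its study samples. Layouts default to 158 study +
21 QC per GC batch and 264 + 24 per LC batch; the batch count is
ceil(n_platform_samples / real_per_batch). Per-platform sample counts
(`n_gc_samples`, `n_lc_samples`) allow partially overlapping platform
cohorts; the overlap forms the mixture-analysis cohort.

**Outcomes.** Disease indicators are drawn from a logistic model on
centred log10 true concentration (configurable log-OR per log10 ng/mL;
defaults in the modest 0.3–0.7 range) plus a mild age term, then
realised by writing the outcome's clinical parameter just above or below
its diagnostic threshold — so the classifier reproduces the drawn labels
exactly and recovery tests have exact truth. Only single-parameter
outcomes are injectable; composites arise from their components.

**What the generator does not emulate** — and hence what passing tests
do not establish about real data: chromatographic peak shape and
integration error, retention-time drift, matrix suppression, carryover,
within-batch temporal drift (drift is constant within a batch except
where tests construct otherwise), correlated exposure sources, and
selection/consent biases in cohort assembly.

## 2. Quantification

* Weighted fit via `statsmodels` WLS with weights 1/C; the zero
  calibrator is excluded (weight undefined at C = 0) and kept only for
  blank checks. r² is computed on the weighted scale (1 − SSE_w/SST_w),
  consistent with the 1/x objective; no r² acceptance floor is enforced,
  it is reported only.
* A curve needs ≥ 5 distinct positive calibrator levels, otherwise the
  (chemical, batch) is flagged unquantifiable; an all-identical design
  raises a singular-design error; a non-positive slope is flagged, not
  accepted.
* LOQ is estimated per batch (lowest ladder level with mean area /
  noise_sd > 10, strict), with a study-level override available; if no
  level qualifies the LOQ is +∞ and the chemical is 0% detected in that
  batch rather than dropped study-wide.
* Back-calculation uses only the sample's own batch curve. Negative or
  below-LOQ values are flagged censored; imputation writes LOQ/√2 and
  never touches the flags, so detection frequencies are imputation-
  invariant. Cells with infinite LOQ use an optional ceiling value or
  remain missing.
* GC IS assignment is static nearest retention time (ties to the
  earlier-eluting standard); LC assignment minimises the RSD of
  IS-corrected, batch-quantified QC concentrations, computed per spike
  level and averaged, evaluated once on all QCs and then frozen. With no
  candidates the chemical falls back to the external-standard mode (raw
  area calibration) with a logged warning.

## 3. Quality control

The batch-effect scalar is a one-way ANOVA R² (between-batch SS / total
SS) of log10 QC values, averaged over chemicals — chosen because it
yields a single testable number while PCA score tables remain available
for plotting. RSD is computed on quantified concentrations, not raw
areas, matching how batch-specific QC quantification is meant to be
judged. Total variance at float-epsilon level is treated as exactly
zero so a perfectly corrected QC matrix scores 0, not noise/noise.

## 4. Outcomes and matching

All twelve thresholds are applied exactly as printed; every rule is ≥
except obesity (BMI strictly > 28 kg/m²). Missing parameters propagate
as missing labels under Kleene logic (never false). The metabolic-
syndrome rule is monotone in its four components (property-tested).
Matching: propensity from a logistic model on the nine epidemiological
factors plus the five major diseases (obesity, hypertension, diabetes,
hyperuricemia, hyperlipidemia; any indicator degenerate given case
status is dropped to avoid quasi-separation), greedy 1:1 nearest
neighbour without replacement on the **logit** of the score (raw-scale
option available), cases in descending score order, no caliper by
default (a caliper is exposed as an option). Cases with more than two
diseases are excluded except for metabolic syndrome. Education enters
the propensity and risk models as an integer ordinal score — the
simplest faithful encoding.

## 5. Characterisation

Detection means "measured and not below LOQ"; the high-frequency rule is
strictly > 50% in at least one region. Geometric-mean CIs use a
log-scale t interval (the conventional choice where none is prescribed).
Group differences use two-sided rank-sum tests with Benjamini–Hochberg
control and a 0.8/1.3 fold-change screen. Partial Spearman correlations
residualise rank-transformed variables on rank-transformed confounders
by least squares, with a t-approximation on n − 2 − k df. Variance
partitioning reports both the marginal fraction (per-factor adjusted R²,
averaged over chemicals of the standardised log10 matrix) and the unique
fraction (joint minus leave-one-out), since published single numbers are
rarely attributable to one convention. PCA is a plain SVD of the
standardised log10 matrix with a deterministic sign convention;
zero-variance columns are dropped with a warning.

## 6. Risk models

Single-exposure fits are GLM/Binomial (IRLS) — markedly more robust than
Newton on matched sets with many dummy covariates — with nuisance
covariates z-scored for conditioning (this leaves the exposure
coefficient unchanged). Non-convergence or separation (se > 10³ per
log10 unit) yields a flagged result, never a number. Wald CIs
exp(β ± 1.96·se) are the default. Hosmer–Lemeshow p values are reported
as a diagnostic only, never used for filtering. Age strata are
half-open [30, 50), [50, 60) and closed [60, 80] — so age 50 falls in
"50–60" — and are configurable.

**WQS** (from scratch): simplex-constrained maximisation of the logistic
likelihood in β·(Qw) plus covariates via SLSQP with analytic gradients,
one direction per run (β ≥ 0 or ≤ 0); 40/60 train/validation split with
a seeded shuffle; per-bootstrap weights aggregated with weight
proportional to the bootstrap index |t| statistic (a common WQS
convention; a plain mean is switchable); the final index is refit on the
validation split. More than 50% failed bootstraps flags the result
unstable. The OR confidence interval is reported two ways: the literal
OR-scale formula OR ± 1.96·SE(OR) — kept as the default for fidelity to
the convention printed in the biomonitoring literature this package
follows, although it is statistically unconventional (it can cross
zero) — and the standard exp(β ± 1.96·se).

**Quantile g-computation** (from scratch): one GLM on all quartile
scores plus covariates; ψ = Σ coefficients with delta-method se
(1ᵀΣ1); positive/negative weights normalised within direction;
collinear designs fall back to a ridge-stabilised fit with a warning.
Quartile cut points assign ties to the lowest class and are stored for
reuse on new data. Mixture covariates are {region, age, sex, smoking,
drinking}; the mixture cohort is restricted to subjects measured on both
platforms and chemicals with nationwide detection > 50%. BKMR is not
implemented; the interface says so explicitly.

**Risk assessment**: HQ = C/C_guidance with strict HQ > 1 exceedance.
RfD-type (intake-based) guidance values are used only when supplied as
serum-equivalents; no pharmacokinetic conversion is computed. Dose–risk
curves use a restricted cubic spline of log10 concentration with knots
at the 5/35/65/95% quantiles (a standard placement), anchored at the
sample median (OR = 1 there by construction; the anchor is included in
the output grid). The minimum risk dose is the smallest grid
concentration above the anchor with a sustained point-estimate OR > 1;
requiring the CI lower bound instead is an option.

## 7. Problem sizes and reproducibility

Default analysis sizes — 800 subjects and 20 chemicals for the worked
pipeline; 500 × 20 × 3 batches for quantification recovery; n = 5000
for odds-ratio recovery; 100 replicates of n = 2000 for null coverage;
200 bootstraps for WQS weight recovery; 4582 + 5280 platform samples for
the 29 + 20 = 49-curve structural check — were chosen as the smallest
designs at which each property is comfortably identified. All
randomness flows from explicit seeds through `numpy` Generators; the
pipeline manifest records SHA-256 hashes of every output, and reruns
with the same configuration are byte-identical.

## 8. Known limitations

Single imputation at LOQ/√2 understates censoring uncertainty; greedy
matching is order-dependent (mitigated by the descending-score
convention) and not globally optimal; the WQS split-sample design
halves the data each side; variance-partitioning fractions from
correlated factors (region vs sampling month) overlap and should be
read jointly; dose–risk curves extrapolate poorly beyond the observed
concentration range and are truncated to it.
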