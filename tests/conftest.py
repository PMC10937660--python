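import numpy as np
import pandas as pd
import pytest

from exposome import (
    BatchLayout,
    StudyConfig,
    default_panel,
    generate_cohort,
    generate_exposures,
    generate_peak_tables,
    generate_study,
)
from exposome.simulate import _rng


def small_config(**overrides) -> StudyConfig:
    base = dict(
        n_subjects=150,
        n_chemicals_gc=6,
        n_chemicals_lc=4,
        batch_layout_gc=BatchLayout(50, 8),
        batch_layout_lc=BatchLayout(75, 9),
        noise_cv=0.05,
        drift_sd_log10=0.15,
        seed=7,
    )
    base.update(overrides)
    return StudyConfig(**base)


@pytest.fixture(scope="session")
def tiny_bundle():
    """Small noisy study used across modules."""
    return generate_study(small_config())


@pytest.fixture(scope="session")
def noiseless_bundle():
    """Zero area noise: quantification should be exact."""
    return generate_study(small_config(noise_cv=0.0, seed=11))


@pytest.fixture(scope="session")
def recovery_bundle():
    """500 subjects, 20 chemicals, 3 batches per platform, drift up to 3x,
    zero noise -- the exact-recovery study design."""
    cfg = small_config(
        n_subjects=500, n_chemicals_gc=12, n_chemicals_lc=8,
        batch_layout_gc=BatchLayout(167, 7), batch_layout_lc=BatchLayout(167, 7),
        noise_cv=0.0, seed=29)
    panel = default_panel(cfg, _rng(cfg.seed, "panel"))
    cohort = generate_cohort(cfg)
    truth = generate_exposures(cohort, cfg, panel)
    for platform in truth.batch_drift:
        drift = truth.batch_drift[platform]
        for i, factor in enumerate((1.0, 0.5, 3.0)):
            if i < len(drift.index):
                drift.iloc[i, :] = factor
    peaks = generate_peak_tables(truth, cfg, panel)
    from exposome.simulate import StudyBundle
    return StudyBundle(cohort=cohort, peak_tables=peaks, panel=panel,
                       truth=truth, config=cfg)


@pytest.fixture(scope="session")
def noisy_recovery_bundle():
    """Same design with 5% area CV."""
    cfg = small_config(
        n_subjects=500, n_chemicals_gc=12, n_chemicals_lc=8,
        batch_layout_gc=BatchLayout(167, 7), batch_layout_lc=BatchLayout(167, 7),
        noise_cv=0.05, seed=29)
    panel = default_panel(cfg, _rng(cfg.seed, "panel"))
    cohort = generate_cohort(cfg)
    truth = generate_exposures(cohort, cfg, panel)
    for platform in truth.batch_drift:
        drift = truth.batch_drift[platform]
        for i, factor in enumerate((1.0, 0.5, 3.0)):
            if i < len(drift.index):
                drift.iloc[i, :] = factor
    peaks = generate_peak_tables(truth, cfg, panel)
    from exposome.simulate import StudyBundle
    return StudyBundle(cohort=cohort, peak_tables=peaks, panel=panel,
                       truth=truth, config=cfg)


@pytest.fixture(scope="session")
def quantified(tiny_bundle):
    from exposome import impute_below_loq, quantify_study
    res = quantify_study(tiny_bundle.peak_tables, tiny_bundle.panel,
                         noise_sd=tiny_bundle.truth.noise_floor)
    return res, impute_below_loq(res.matrix)


def make_outcome(lin_pred: np.ndarray, seed: int) -> np.ndarray:
    """Bernoulli draw through the logistic link."""
    from scipy.special import expit
    rng = np.random.default_rng(seed)
    return (rng.random(len(lin_pred)) < expit(np.asarray(lin_pred))).astype(float)
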