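"""Calibration fitting, LOQ, IS selection, and back-calculation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exposome import (
    estimate_loq,
    fit_calibration,
    impute_below_loq,
    quantify_study,
    select_internal_standard,
)
from exposome.quantify import ConcentrationMatrix, SingularDesignError, \
    evaluate_curve_accuracy


def weighted_normal_equations(x, y, w):
    """Independent closed-form WLS oracle: solve the 2x2 normal equations."""
    x, y, w = map(np.asarray, (x, y, w))
    A = np.array([[w.sum(), (w * x).sum()], [(w * x).sum(), (w * x * x).sum()]])
    b = np.array([(w * y).sum(), (w * x * y).sum()])
    intercept, slope = np.linalg.solve(A, b)
    return intercept, slope


class TestFitCalibration:
    def test_exact_proportional_data(self):
        x = [0.1, 1, 5, 10, 100]
        y = [0.05, 0.5, 2.5, 5, 50]
        fit = fit_calibration(x, y)
        assert fit.ok
        assert fit.slope == pytest.approx(0.5, abs=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_exact_affine_data(self):
        x = np.array([0.5, 1, 2, 5, 10])
        fit = fit_calibration(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0, abs=1e-10)
        assert fit.intercept == pytest.approx(1.0, abs=1e-10)

    def test_matches_weighted_normal_equations(self):
        rng = np.random.default_rng(5)
        x = np.array([0.1, 0.5, 1, 5, 20, 100.0])
        y = 0.8 * x + 0.05 + rng.normal(0, 0.02, 6) * x  # noise ~ x
        fit = fit_calibration(x, y)
        b0, b1 = weighted_normal_equations(x, y, 1.0 / x)
        assert fit.intercept == pytest.approx(b0, abs=1e-10)
        assert fit.slope == pytest.approx(b1, abs=1e-10)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_random_designs_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(6, 14)
        x = np.sort(rng.uniform(0.01, 100, n))
        y = rng.uniform(0.1, 3) * x + rng.normal(0, 0.1, n)
        fit = fit_calibration(x, y)
        if fit.ok:
            b0, b1 = weighted_normal_equations(x, y, 1.0 / x)
            assert fit.intercept == pytest.approx(b0, abs=1e-9)
            assert fit.slope == pytest.approx(b1, abs=1e-9)

    def test_zero_level_excluded_from_fit(self):
        x = [0.0, 0.5, 1, 2, 5, 10]
        y = np.array(x) * 3.0
        y[0] = 99.0  # blank contamination must not influence the fit
        fit = fit_calibration(x, y)
        assert fit.slope == pytest.approx(3.0, abs=1e-10)

    def test_too_few_levels_flagged(self):
        fit = fit_calibration([1, 2, 5, 10], [1, 2, 5, 10])
        assert not fit.ok and fit.reason == "insufficient_levels"

    def test_identical_levels_raise(self):
        with pytest.raises(SingularDesignError):
            fit_calibration([2, 2, 2, 2, 2], [1, 2, 3, 4, 5])


class TestLOQ:
    def test_threshold_application(self):
        # S/N = {0.5, 2.5, 6.0, 10.5}: first strict exceedance at 0.2 ng/mL
        loq = estimate_loq([0.02, 0.05, 0.1, 0.2], [5, 25, 60, 105], noise_sd=10)
        assert loq == 0.2

    def test_vanishing_noise_gives_lowest_level(self):
        loq = estimate_loq([0.02, 0.05, 0.1], [1, 2, 3], noise_sd=1e-12)
        assert loq == 0.02

    def test_no_level_qualifies(self):
        assert estimate_loq([0.02, 0.05], [5, 10], noise_sd=1.0) == math.inf

    def test_boundary_is_strict(self):
        # S/N exactly 10 does not qualify
        assert estimate_loq([1.0, 2.0], [100.0, 300.0], noise_sd=10.0) == 2.0

    def test_input_errors(self):
        with pytest.raises(ValueError):
            estimate_loq([], [], noise_sd=1.0)
        with pytest.raises(ValueError):
            estimate_loq([1.0], [5.0], noise_sd=0.0)


def _is_selection_records(qc_drift_by_candidate, calib_levels=(0.5, 1, 2, 5, 10),
                          qc_level=2.0, analyte_qc_drift=(1.0, 2.0), noise=0.0,
                          seed=0):
    """Two-batch LC records where QCs drift relative to the calibrators.

    Candidate ISs whose QC areas share the analyte's QC-time drift cancel
    it; others leave it in the quantified QC concentrations.
    """
    rng = np.random.default_rng(seed)
    rows = []
    candidates = list(qc_drift_by_candidate)
    for b, adrift in zip(("B1", "B2"), analyte_qc_drift):
        for i, lv in enumerate(calib_levels):
            sid = f"{b}_CAL{i}"
            area = 100.0 * lv * (1 + rng.normal(0, noise))
            rows.append((sid, "calibrator", b, "chem", area, lv))
            for cand in candidates:
                rows.append((sid, "calibrator", b, cand,
                             1000.0 * (1 + rng.normal(0, noise)), lv))
        for j in range(3):
            sid = f"{b}_QC{j}"
            rows.append((sid, "qc", b, "chem",
                         100.0 * qc_level * adrift * (1 + rng.normal(0, noise)),
                         qc_level))
            for cand in candidates:
                d = qc_drift_by_candidate[cand](adrift)
                rows.append((sid, "qc", b, cand,
                             1000.0 * d * (1 + rng.normal(0, noise)), qc_level))
    df = pd.DataFrame(rows, columns=["sample_id", "role", "batch",
                                     "chemical_id", "area", "nominal"])
    areas = df.pivot_table(index="sample_id", columns="chemical_id", values="area")
    meta = df.drop_duplicates("sample_id").set_index("sample_id")[
        ["role", "batch", "nominal"]]
    return areas, meta.loc[areas.index]


class TestISSelection:
    def test_gc_nearest_retention_time(self, tiny_bundle):
        panel = tiny_bundle.panel
        chem = panel.by_platform("GC")[0]
        chosen = select_internal_standard(chem.chemical_id, chem.candidate_is,
                                          "gc_rt", panel=panel)
        rts = {i: abs(panel.internal_standard(i).rt - chem.rt)
               for i in chem.candidate_is}
        assert chosen == min(rts, key=lambda i: (rts[i], panel.internal_standard(i).rt))

    def test_shared_drift_candidate_wins_noiseless(self):
        areas, meta = _is_selection_records({
            "IS_share": lambda d: d,      # follows the analyte's QC drift
            "IS_flat": lambda d: 1.0,     # does not
        })
        chosen = select_internal_standard("chem", ["IS_flat", "IS_share"],
                                          "lc_min_rsd", areas=areas, meta=meta)
        assert chosen == "IS_share"

    def test_argmin_matches_bruteforce_rsd(self):
        drifts = {"IS_a": lambda d: d, "IS_b": lambda d: 1.0,
                  "IS_c": lambda d: d ** 0.5}
        areas, meta = _is_selection_records(drifts, noise=0.03, seed=42)
        chosen = select_internal_standard("chem", list(drifts), "lc_min_rsd",
                                          areas=areas, meta=meta)
        # brute-force oracle: per-candidate RSD of batch-quantified QCs
        rsds = {}
        for cand in drifts:
            concs = []
            for b in ("B1", "B2"):
                cal = meta.index[(meta["batch"] == b) & (meta["role"] == "calibrator")]
                ratio = areas["chem"] / areas[cand]
                b0, b1 = weighted_normal_equations(
                    meta.loc[cal, "nominal"], ratio.loc[cal],
                    1.0 / meta.loc[cal, "nominal"].to_numpy())
                qs = meta.index[(meta["batch"] == b) & (meta["role"] == "qc")]
                concs.extend((ratio.loc[qs] - b0) / b1)
            concs = np.array(concs)
            rsds[cand] = concs.std(ddof=1) / concs.mean()
        assert chosen == min(rsds, key=rsds.get)

    def test_no_candidates_falls_back_to_external(self):
        assert select_internal_standard("chem", [], "lc_min_rsd") == "external"


class TestQuantification:
    def test_inversion_per_batch(self, noiseless_bundle):
        res = quantify_study(noiseless_bundle.peak_tables, noiseless_bundle.panel,
                             noise_sd=noiseless_bundle.truth.noise_floor)
        chem = noiseless_bundle.panel.by_platform("GC")[0].chemical_id
        fits = {b: f for (c, b), f in res.fits.items() if c == chem}
        assert len(fits) >= 2
        for f in fits.values():
            assert f.ok and f.r2 == pytest.approx(1.0, abs=1e-10)

    def test_noiseless_recovery_matches_truth(self, recovery_bundle):
        truth = recovery_bundle.truth
        res = quantify_study(recovery_bundle.peak_tables, recovery_bundle.panel,
                             noise_sd=truth.noise_floor)
        vals = res.matrix.values
        errs = []
        for chem in vals.columns:
            m = ~res.matrix.below_loq[chem] & vals[chem].notna()
            if m.any():
                t = truth.true_concentration.loc[vals.index[m], chem].to_numpy()
                errs.append(np.abs(vals.loc[m, chem].to_numpy() / t - 1).max())
        assert max(errs) < 1e-6

    def test_drift_immunity_of_is_correction(self, noiseless_bundle):
        """Post-calibration drift (study rows scaled, calibrators untouched)
        cancels under IS correction but not under external calibration."""
        import copy
        bundle = noiseless_bundle
        peaks = {k: v.copy() for k, v in bundle.peak_tables.items()}
        gc = peaks["GC"]
        b = gc["batch"].iloc[-1]
        scale = (gc["batch"] == b) & (gc["role"] == "study")
        gc.loc[scale, "area"] *= 3.7
        gc.loc[scale & gc["is_area"].notna(), "is_area"] *= 3.7

        base = quantify_study(bundle.peak_tables, bundle.panel,
                              noise_sd=bundle.truth.noise_floor)
        drifted = quantify_study(peaks, bundle.panel,
                                 noise_sd=bundle.truth.noise_floor)
        pd.testing.assert_frame_equal(base.matrix.values, drifted.matrix.values)

        # external-standard mode is NOT immune
        gc_chems = [c.chemical_id for c in bundle.panel.by_platform("GC")]
        ext_panel = copy.deepcopy(bundle.panel)
        ext_panel.chemicals = [
            (c if c.platform != "GC" else
             type(c)(chemical_id=c.chemical_id, platform=c.platform,
                     category=c.category, rt=c.rt, candidate_is=()))
            for c in ext_panel.chemicals]
        base_e = quantify_study(bundle.peak_tables, ext_panel,
                                noise_sd=bundle.truth.noise_floor)
        drift_e = quantify_study(peaks, ext_panel,
                                 noise_sd=bundle.truth.noise_floor)
        in_b = base_e.matrix.batch[gc_chems[0]] == b
        changed = (drift_e.matrix.values.loc[in_b, gc_chems]
                   / base_e.matrix.values.loc[in_b, gc_chems])
        assert np.nanmedian(changed.to_numpy()) == pytest.approx(3.7, rel=1e-6)

    def test_monotone_in_analyte_area(self, noiseless_bundle):
        """Raising a study sample's analyte area (IS fixed) never lowers its
        back-calculated concentration."""
        peaks = {k: v.copy() for k, v in noiseless_bundle.peak_tables.items()}
        gc = peaks["GC"]
        chem = noiseless_bundle.panel.by_platform("GC")[0].chemical_id
        row = gc[(gc["chemical_id"] == chem) & (gc["role"] == "study")].index[0]
        base = quantify_study(noiseless_bundle.peak_tables, noiseless_bundle.panel,
                              noise_sd=noiseless_bundle.truth.noise_floor)
        gc.loc[row, "area"] *= 1.5
        more = quantify_study(peaks, noiseless_bundle.panel,
                              noise_sd=noiseless_bundle.truth.noise_floor)
        sid = gc.loc[row, "sample_id"]
        assert more.matrix.values.loc[sid, chem] >= base.matrix.values.loc[sid, chem]


class TestImputation:
    def _matrix(self):
        vals = pd.DataFrame({"c1": [np.nan, 0.06, np.nan], "c2": [1.0, 2.0, 3.0]},
                            index=["s1", "s2", "s3"])
        below = pd.DataFrame({"c1": [True, False, True], "c2": [False] * 3},
                             index=vals.index)
        loq = pd.DataFrame({"c1": [0.05] * 3, "c2": [0.1] * 3}, index=vals.index)
        batch = pd.DataFrame("B1", index=vals.index, columns=vals.columns)
        return ConcentrationMatrix(values=vals, below_loq=below, loq=loq,
                                   batch=batch)

    def test_below_loq_cells_get_loq_over_sqrt2(self):
        out = impute_below_loq(self._matrix())
        assert out.values.loc["s1", "c1"] == pytest.approx(0.05 / math.sqrt(2),
                                                           abs=1e-15)
        assert out.values.loc["s2", "c1"] == 0.06  # above LOQ: untouched
        pd.testing.assert_frame_equal(out.below_loq, self._matrix().below_loq)

    def test_infinite_loq_uses_ceiling_or_stays_missing(self):
        m = self._matrix()
        m.loq.loc[:, "c1"] = math.inf
        out = impute_below_loq(m)
        assert out.values["c1"].isna().all() or not out.values["c1"].loc[["s1", "s3"]].notna().any()
        out2 = impute_below_loq(m, ceiling_loq=100.0)
        assert out2.values.loc["s1", "c1"] == pytest.approx(100 / math.sqrt(2))


class TestAccuracy:
    def test_accuracy_bands(self):
        qc = pd.DataFrame({
            "chemical_id": ["c"] * 3, "batch": ["B1"] * 3, "platform": ["GC"] * 3,
            "nominal": [2.0, 2.0, 5.0], "conc": [2.1, 2.1, 3.75]})
        out = evaluate_curve_accuracy(qc).set_index("nominal")
        assert out.loc[2.0, "accuracy_pct"] == pytest.approx(105.0)
        assert bool(out.loc[2.0, "pass"])
        assert out.loc[5.0, "accuracy_pct"] == pytest.approx(75.0)
        assert not bool(out.loc[5.0, "pass"])

    def test_noiseless_batches_are_exact(self, noiseless_bundle):
        res = quantify_study(noiseless_bundle.peak_tables, noiseless_bundle.panel,
                             noise_sd=noiseless_bundle.truth.noise_floor)
        acc = res.accuracy
        assert not acc.empty
        np.testing.assert_allclose(acc["accuracy_pct"], 100.0, rtol=1e-8)
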