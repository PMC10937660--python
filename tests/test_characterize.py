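"""Detection frequencies, summaries, group differences, correlations,
variance partitioning and PCA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from exposome.characterize import (
    detection_frequency,
    geometric_summary,
    partial_spearman,
    pca_scores,
    select_high_frequency,
    stratified_differences,
    variance_partition,
)
from exposome.quantify import ConcentrationMatrix


def _matrix(values, flags=None, regions=None):
    vals = pd.DataFrame(values)
    below = pd.DataFrame(False, index=vals.index, columns=vals.columns) \
        if flags is None else pd.DataFrame(flags)
    batch = pd.DataFrame("B1", index=vals.index, columns=vals.columns)
    loq = pd.DataFrame(0.01, index=vals.index, columns=vals.columns)
    m = ConcentrationMatrix(values=vals, below_loq=below, loq=loq, batch=batch)
    reg = pd.Series(regions if regions is not None else "R1", index=vals.index)
    return m, reg


class TestDetection:
    def test_frequency_arithmetic(self):
        m, reg = _matrix({"c": np.ones(8)},
                         flags={"c": [False] * 6 + [True] * 2})
        out = detection_frequency(m, reg)
        assert out.loc["c", "freq_total"] == pytest.approx(75.0)

    def test_all_below_loq(self):
        m, reg = _matrix({"c": np.ones(5)}, flags={"c": [True] * 5})
        assert detection_frequency(m, reg).loc["c", "freq_total"] == 0.0

    def test_high_frequency_rule_is_strict(self):
        # region frequencies exactly 50% must NOT qualify; 50.1% must
        flags = {"c": [False, True] * 10}   # 50% in every region
        regions = ["R1"] * 10 + ["R2"] * 10
        m, reg = _matrix({"c": np.ones(20)}, flags=flags, regions=regions)
        out = detection_frequency(m, reg)
        assert not bool(out.loc["c", "high_frequency"])
        assert select_high_frequency(out) == []
        flags2 = {"c": [False] * 11 + [True] * 9}  # R1: 6/10 detected
        m2, reg2 = _matrix({"c": np.ones(20)}, flags=flags2, regions=regions)
        out2 = detection_frequency(m2, reg2)
        assert select_high_frequency(out2) == ["c"]

    def test_selection_recovers_configured_targets(self):
        from conftest import small_config
        from exposome import generate_study, impute_below_loq, quantify_study
        cfg = small_config(n_subjects=2000, n_chemicals_gc=3, n_chemicals_lc=1,
                           detection_targets=(0.20, 0.60, 0.90), seed=23,
                           regions=("A",))
        bundle = generate_study(cfg)
        res = quantify_study(bundle.peak_tables, bundle.panel,
                             noise_sd=bundle.truth.noise_floor)
        reg = bundle.cohort.set_index("subject_id")["region"]
        out = detection_frequency(res.matrix, reg)
        selected = select_high_frequency(out)
        assert set(selected) >= {"GC_002", "GC_003"}
        assert "GC_001" not in selected

    def test_frequency_invariant_to_monotone_rescaling(self):
        m, reg = _matrix({"c": [1.0, 2, 3, 4]}, flags={"c": [True, False, False, True]})
        base = detection_frequency(m, reg)
        m2 = ConcentrationMatrix(values=m.values ** 3 * 10, below_loq=m.below_loq,
                                 loq=m.loq, batch=m.batch)
        pd.testing.assert_frame_equal(base, detection_frequency(m2, reg))


class TestGeometricSummary:
    def test_symmetric_logs(self):
        out = geometric_summary([1.0, 10.0, 100.0])
        assert out["gm"] == pytest.approx(10.0, rel=1e-12)

    def test_constant_vector_collapses(self):
        out = geometric_summary([3.3] * 7)
        assert out["gm"] == pytest.approx(3.3)
        assert out["ci_low"] == pytest.approx(3.3)
        assert out["ci_high"] == pytest.approx(3.3)

    def test_matches_log_t_interval_oracle(self):
        rng = np.random.default_rng(1)
        v = rng.lognormal(0.5, 0.8, 500)
        out = geometric_summary(v)
        logs = np.log(v)
        half = stats.t.ppf(0.975, 499) * logs.std(ddof=1) / np.sqrt(500)
        assert out["gm"] == pytest.approx(np.exp(logs.mean()), abs=1e-10)
        assert out["ci_low"] == pytest.approx(np.exp(logs.mean() - half), abs=1e-10)
        assert out["ci_high"] == pytest.approx(np.exp(logs.mean() + half), abs=1e-10)
        assert out["median"] == np.median(v)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            geometric_summary([1.0, 0.0, 2.0])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(1e-3, 1e3), min_size=2, max_size=30))
    def test_gm_never_exceeds_arithmetic_mean(self, values):
        out = geometric_summary(values)
        assert out["gm"] <= np.mean(values) * (1 + 1e-12)


class TestStratifiedDifferences:
    def test_identical_groups_fc_one(self):
        rng = np.random.default_rng(2)
        v = rng.lognormal(0, 0.5, 20)
        vals = pd.DataFrame({"c": np.r_[v, v]})
        grouping = pd.Series(["a"] * 20 + ["b"] * 20)
        out = stratified_differences(vals, grouping, "a", "b")
        assert out.loc["c", "fold_change"] == pytest.approx(1.0)
        assert not bool(out.loc["c", "notable"])

    def test_doubling_gives_fc_two(self):
        rng = np.random.default_rng(3)
        v = rng.lognormal(0, 0.5, 15)
        vals = pd.DataFrame({"c": np.r_[2 * v, v]})
        grouping = pd.Series(["a"] * 15 + ["b"] * 15)
        out = stratified_differences(vals, grouping, "a", "b")
        assert out.loc["c", "fold_change"] == pytest.approx(2.0, rel=1e-10)

    def test_bh_adjustment_matches_stepup_oracle(self):
        rng = np.random.default_rng(4)
        n = 40
        cols = {f"null{i}": rng.lognormal(0, 0.4, 2 * n) for i in range(18)}
        for i in range(2):
            shifted = np.r_[rng.lognormal(1.0, 0.4, n), rng.lognormal(0, 0.4, n)]
            cols[f"shift{i}"] = shifted
        vals = pd.DataFrame(cols)
        grouping = pd.Series(["a"] * n + ["b"] * n)
        out = stratified_differences(vals, grouping, "a", "b")
        # step-up oracle by hand
        p = out["p"].to_numpy()
        m = len(p)
        order = np.argsort(p)
        q_sorted = p[order] * m / (np.arange(m) + 1)
        q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
        q = np.empty(m)
        q[order] = np.minimum(q_sorted, 1.0)
        np.testing.assert_allclose(out["q"], q, atol=1e-12)
        assert (np.diff(np.sort(out["q"])[np.argsort(np.argsort(p))][order]) >= -1e-12).all()
        assert (out["q"] >= out["p"] - 1e-12).all()


def _cohort_frame(n, rng):
    return pd.DataFrame({
        "age": rng.uniform(20, 80, n),
        "income": rng.lognormal(9, 1, n),
    })


class TestPartialSpearman:
    def test_exact_monotone_gives_rho_one(self):
        rng = np.random.default_rng(5)
        coh = _cohort_frame(100, rng)
        vals = pd.DataFrame({"c": np.exp(coh["age"] / 10)})
        out = partial_spearman(vals, coh, "age", [])
        assert out.loc["c", "rho"] == pytest.approx(1.0)

    def test_independent_factor_rho_near_zero(self):
        rng = np.random.default_rng(6)
        coh = _cohort_frame(1000, rng)
        vals = pd.DataFrame({"c": rng.lognormal(0, 1, 1000)})
        out = partial_spearman(vals, coh, "age", ["income"])
        assert abs(out.loc["c", "rho"]) < 0.08

    def test_confounder_induced_correlation_attenuates(self):
        rng = np.random.default_rng(7)
        n = 800
        u = rng.normal(0, 1, n)           # confounder drives both
        coh = pd.DataFrame({"age": 50 + 10 * u + rng.normal(0, 2, n),
                            "income": np.exp(9 + u + rng.normal(0, 0.2, n))})
        vals = pd.DataFrame({"c": np.exp(u + rng.normal(0, 0.3, n))})
        marginal = stats.spearmanr(coh["age"], vals["c"]).statistic
        partial = partial_spearman(vals, coh, "age", ["income"]).loc["c", "rho"]
        assert abs(partial) < abs(marginal)


class TestVariancePartition:
    def test_saturated_binary_factor(self):
        n = 200
        g = np.r_[np.zeros(n // 2), np.ones(n // 2)]
        vals = pd.DataFrame({"c": 10.0 ** (1 + g)})  # all variance between groups
        coh = pd.DataFrame({"grp": g})
        out = variance_partition(vals, coh, ["grp"])
        assert out.loc["grp", "marginal"] == pytest.approx(1.0, abs=1e-10)

    def test_independent_factor_near_zero(self):
        rng = np.random.default_rng(8)
        n = 1000
        vals = pd.DataFrame({"c": rng.lognormal(0, 0.5, n)})
        coh = pd.DataFrame({"x": rng.normal(0, 1, n)})
        out = variance_partition(vals, coh, ["x"])
        assert abs(out.loc["x", "marginal"]) < 0.02

    def test_region_dominates_age_when_generated_so(self):
        from conftest import small_config
        from exposome import default_panel, generate_cohort, generate_exposures
        from exposome.simulate import _rng
        cfg = small_config(n_subjects=1200, region_sd_log10=0.5,
                           age_slope_mean=0.002, age_slope_sd=0.0, seed=31)
        panel = default_panel(cfg, _rng(cfg.seed, "panel"))
        cohort = generate_cohort(cfg)
        truth = generate_exposures(cohort, cfg, panel)
        out = variance_partition(truth.true_concentration,
                                 cohort, ["region", "age"])
        assert out.loc["region", "marginal"] > out.loc["age", "marginal"]


class TestPCA:
    def test_rank_one_data(self):
        rng = np.random.default_rng(9)
        t = rng.normal(0, 1, 50)
        vals = pd.DataFrame(10.0 ** np.outer(t, [1.0, 2.0, -1.0]))
        _, _, expl = pca_scores(vals)
        assert expl.iloc[0] == pytest.approx(1.0, abs=1e-10)

    def test_loadings_orthonormal_and_reconstruction(self, quantified):
        _, mat = quantified
        scores, loadings, expl = pca_scores(mat.values)
        gram = loadings.to_numpy().T @ loadings.to_numpy()
        np.testing.assert_allclose(gram, np.eye(gram.shape[0]), atol=1e-8)
        X = np.log10(mat.values.to_numpy())
        X = (X - X.mean(0)) / X.std(0)
        np.testing.assert_allclose(scores.to_numpy() @ loadings.to_numpy().T,
                                   X, atol=1e-8)
        assert expl.sum() == pytest.approx(1.0)

    def test_scores_match_svd_oracle_up_to_sign(self, quantified):
        _, mat = quantified
        scores, _, _ = pca_scores(mat.values)
        X = np.log10(mat.values.to_numpy())
        X = (X - X.mean(0)) / X.std(0)
        U, S, Vt = np.linalg.svd(X, full_matrices=False)
        oracle = U * S
        for j in range(scores.shape[1]):
            col = scores.iloc[:, j].to_numpy()
            assert (np.allclose(col, oracle[:, j], atol=1e-8)
                    or np.allclose(col, -oracle[:, j], atol=1e-8))
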