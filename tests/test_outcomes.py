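"""Disease classification rules and propensity matching."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exposome.outcomes import (
    ClassificationError,
    classify_outcomes,
    covariate_balance,
    match_controls,
)
from conftest import small_config
from exposome import generate_cohort, generate_study


def patient(**kw):
    base = dict(subject_id="p1", sex="M", age=50, region="A",
                sampling_month="Aug", education="primary", income=20000,
                marital_status="married", smoking="no", drinking="no",
                uric_acid=300.0, hba1c=5.0, ldl_c=2.0, triglycerides=1.0,
                total_cholesterol=4.0, sbp=120.0, dbp=70.0, waistline=80.0,
                bmi=22.0)
    base.update(kw)
    return pd.DataFrame([base])


# (field overrides, outcome, expected label) around each printed threshold
BOUNDARY_CASES = [
    (dict(sex="M", uric_acid=420.0), "hyperuricemia", True),
    (dict(sex="M", uric_acid=419.9), "hyperuricemia", False),
    (dict(sex="F", uric_acid=360.0), "hyperuricemia", True),
    (dict(sex="F", uric_acid=419.0), "hyperuricemia", True),
    (dict(sex="F", uric_acid=359.9), "hyperuricemia", False),
    (dict(hba1c=6.5), "diabetes", True),
    (dict(hba1c=6.49), "diabetes", False),
    (dict(ldl_c=3.4), "hyper_ldl_c", True),
    (dict(ldl_c=3.39), "hyper_ldl_c", False),
    (dict(triglycerides=2.3), "hypertriglyceridemia", True),
    (dict(triglycerides=2.29), "hypertriglyceridemia", False),
    (dict(total_cholesterol=6.2), "hypercholesterolemia", True),
    (dict(total_cholesterol=6.19), "hypercholesterolemia", False),
    (dict(sbp=140.0), "high_sbp", True),
    (dict(sbp=139.9), "high_sbp", False),
    (dict(dbp=90.0), "high_dbp", True),
    (dict(dbp=89.9), "high_dbp", False),
    (dict(sex="M", waistline=90.0), "abdominal_obesity", True),
    (dict(sex="M", waistline=89.9), "abdominal_obesity", False),
    (dict(sex="F", waistline=85.0), "abdominal_obesity", True),
    (dict(sex="F", waistline=84.9), "abdominal_obesity", False),
    # obesity is the strict inequality: BMI exactly 28 is NOT obese
    (dict(bmi=28.0), "obesity", False),
    (dict(bmi=28.1), "obesity", True),
    (dict(sbp=140.0), "hypertension", True),
    (dict(dbp=90.0), "hypertension", True),
    (dict(sbp=139.0, dbp=89.0), "hypertension", False),
    (dict(ldl_c=3.4), "hyperlipidemia", True),
    (dict(triglycerides=2.3), "hyperlipidemia", True),
    (dict(total_cholesterol=6.2), "hyperlipidemia", True),
    # metabolic syndrome: 3 of 4 components vs 2 of 4
    (dict(sex="M", waistline=95.0, triglycerides=2.5, sbp=150.0), "metabolic_syndrome", True),
    (dict(sex="M", waistline=95.0, triglycerides=2.5, hba1c=7.0), "metabolic_syndrome", True),
    (dict(sex="M", waistline=95.0, triglycerides=2.5), "metabolic_syndrome", False),
]


class TestClassification:
    @pytest.mark.parametrize("overrides,outcome,expected", BOUNDARY_CASES)
    def test_boundary_patients(self, overrides, outcome, expected):
        labels = classify_outcomes(patient(**overrides))
        assert bool(labels[outcome].iloc[0]) is expected

    def test_missing_parameter_propagates_as_missing(self):
        labels = classify_outcomes(patient(hba1c=np.nan))
        assert labels["diabetes"].isna().all()
        assert labels["hyperuricemia"].iloc[0] == False  # unaffected  # noqa: E712

    def test_unknown_sex_code_raises(self):
        with pytest.raises(ClassificationError):
            classify_outcomes(patient(sex="X"))

    def test_composite_invariants_on_random_cohorts(self):
        cohort = generate_cohort(small_config(n_subjects=1500, seed=17))
        lab = classify_outcomes(cohort)
        assert (lab["hypertension"] == (lab["high_sbp"] | lab["high_dbp"])).all()
        assert (lab["hyperlipidemia"] == (lab["hyper_ldl_c"]
                                          | lab["hypertriglyceridemia"]
                                          | lab["hypercholesterolemia"])).all()
        parts = lab[["abdominal_obesity", "hypertriglyceridemia",
                     "hypertension", "diabetes"]]
        n = (parts == True).sum(axis=1)  # noqa: E712
        assert (lab.loc[n >= 3, "metabolic_syndrome"] == True).all()  # noqa: E712
        assert (lab.loc[n < 3, "metabolic_syndrome"] == False).all()  # noqa: E712

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(st.booleans(), min_size=4, max_size=4),
           st.integers(0, 3))
    def test_mets_monotone_in_components(self, flags, flip):
        """Turning one more component on never flips MetS true -> false."""
        def build(f):
            return patient(
                sex="M",
                waistline=95.0 if f[0] else 80.0,
                triglycerides=2.5 if f[1] else 1.0,
                sbp=150.0 if f[2] else 120.0,
                hba1c=7.0 if f[3] else 5.0)
        before = classify_outcomes(build(flags))["metabolic_syndrome"].iloc[0]
        more = list(flags)
        more[flip] = True
        after = classify_outcomes(build(more))["metabolic_syndrome"].iloc[0]
        assert not (bool(before) and not bool(after))


@pytest.fixture(scope="module")
def cohort_labels():
    bundle = generate_study(small_config(
        n_subjects=600, seed=19,
        outcome_effects={"hyperuricemia": {"GC_001": 0.4, "_intercept": -1.0}}))
    return bundle.cohort, classify_outcomes(bundle.cohort)


class TestMatching:
    def test_identical_control_is_chosen(self, cohort_labels):
        cohort, labels = cohort_labels
        m = match_controls(cohort, labels, "hyperuricemia")
        assert len(m.case_ids) == len(m.control_ids)
        assert not (set(m.case_ids) & set(m.control_ids))
        assert len(set(m.control_ids)) == len(m.control_ids)  # no reuse

    def test_greedy_matches_bruteforce_on_two_pairs(self):
        """Scores {0.9, 0.2} vs {0.85, 0.25}: greedy descending-score order
        reproduces the assignment with minimal total distance."""
        from itertools import permutations
        case_scores = {"c1": 0.9, "c2": 0.2}
        ctrl_scores = {"k1": 0.85, "k2": 0.25}
        # greedy: highest case first -> nearest control
        order = sorted(case_scores, key=case_scores.get, reverse=True)
        taken, greedy = set(), {}
        for c in order:
            best = min((k for k in ctrl_scores if k not in taken),
                       key=lambda k: abs(ctrl_scores[k] - case_scores[c]))
            greedy[c] = best
            taken.add(best)
        best_total, best_assign = np.inf, None
        for perm in permutations(ctrl_scores):
            total = sum(abs(case_scores[c] - ctrl_scores[k])
                        for c, k in zip(order, perm))
            if total < best_total:
                best_total, best_assign = total, dict(zip(order, perm))
        assert greedy == best_assign

    def test_multimorbidity_exclusion(self, cohort_labels):
        cohort, labels = cohort_labels
        lab = labels.set_index("subject_id")
        m = match_controls(cohort, labels, "hyperuricemia")
        assert (lab.loc[m.case_ids, "disease_count"] <= 2).all()
        # the exclusion is waived for metabolic syndrome
        if (lab["metabolic_syndrome"] == True).sum() >= 2:  # noqa: E712
            mm = match_controls(cohort, labels, "metabolic_syndrome")
            assert len(mm.case_ids) >= 1

    def test_matching_improves_balance(self, cohort_labels):
        cohort, labels = cohort_labels
        m = match_controls(cohort, labels, "hyperuricemia")
        lab = labels.set_index("subject_id")
        all_cases = list(m.case_ids)
        all_controls = list(lab.index[(lab["hyperuricemia"] == False)])  # noqa: E712
        before = covariate_balance(cohort, all_cases, all_controls)
        after = covariate_balance(cohort, m.case_ids, m.control_ids)
        assert after.mean() <= before.mean() + 0.02

    def test_shortfall_raises(self):
        rows = pd.concat([patient(subject_id=f"p{i}", uric_acid=500.0)
                          for i in range(3)]
                         + [patient(subject_id="q1")], ignore_index=True)
        labels = classify_outcomes(rows)
        with pytest.raises(ValueError, match="short"):
            match_controls(rows, labels, "hyperuricemia")
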