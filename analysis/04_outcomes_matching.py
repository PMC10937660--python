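#!/usr/bin/env python
"""Derive the 12 chronic-disease labels and build matched case-control sets.

Labels follow the printed diagnostic thresholds; matching is greedy 1:1
propensity-score nearest-neighbour on the nine epidemiological factors
plus the five major chronic diseases, with multimorbid cases (> 2
diseases) excluded except for metabolic syndrome.
"""

import os

import pandas as pd

from exposome import read_study_bundle
from exposome.outcomes import (OUTCOMES, classify_outcomes, covariate_balance,
                               match_controls)

ROOT = os.path.join(os.path.dirname(__file__), "..", "results")
bundle = read_study_bundle(os.path.join(ROOT, "bundle"))

labels = classify_outcomes(bundle.cohort)
out = os.path.join(ROOT, "outcomes")
os.makedirs(out, exist_ok=True)
encoded = labels.copy()
for c in encoded.columns:
    if str(encoded[c].dtype) == "boolean":
        encoded[c] = encoded[c].map({True: 1, False: 0}).astype("Int64")
encoded.to_csv(os.path.join(out, "labels.csv"), index=False)

counts = {o: int((labels[o] == True).sum()) for o in OUTCOMES}  # noqa: E712
print("outcome prevalence (cases of", len(labels), "subjects):")
for o, n in counts.items():
    print(f"  {o:22s} {n:4d}")

for outcome in ("hyperuricemia", "hyperlipidemia", "metabolic_syndrome"):
    try:
        m = match_controls(bundle.cohort, labels, outcome)
    except ValueError as exc:
        print(f"{outcome}: not matchable ({exc})")
        continue
    m.pairs().to_csv(os.path.join(out, f"matched_{outcome}.csv"), index=False)
    lab = labels.set_index("subject_id")
    pool_controls = list(lab.index[lab[outcome] == False])  # noqa: E712
    smd_before = covariate_balance(bundle.cohort, m.case_ids, pool_controls)
    smd_after = covariate_balance(bundle.cohort, m.case_ids, m.control_ids)
    print(f"{outcome}: {len(m.case_ids)} pairs, mean |SMD| "
          f"{smd_before.mean():.3f} -> {smd_after.mean():.3f}")
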