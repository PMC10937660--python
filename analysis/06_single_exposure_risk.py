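#!/usr/bin/env python
"""Single-exposure disease-risk models on the matched sets.

Covariate-adjusted logistic regression of hyperuricemia on log10
concentration for every chemical, plus age- and sex-stratified refits
for the top association.
"""

import os

import numpy as np
import pandas as pd

from exposome import read_study_bundle
from exposome.associations import fit_matched, results_frame, stratified_risk
from exposome.outcomes import classify_outcomes, match_controls

ROOT = os.path.join(os.path.dirname(__file__), "..", "results")
bundle = read_study_bundle(os.path.join(ROOT, "bundle"))
vals = pd.read_csv(os.path.join(ROOT, "atlas", "concentrations.csv"),
                   index_col="subject_id")
labels = classify_outcomes(bundle.cohort)

OUTCOME = "hyperuricemia"
matched = match_controls(bundle.cohort, labels, OUTCOME)
results = []
for chem in vals.columns:
    try:
        results.append(fit_matched(matched, vals, bundle.cohort, labels, chem))
    except ValueError:
        pass
frame = results_frame(results)
out = os.path.join(ROOT, "associations")
os.makedirs(out, exist_ok=True)
frame.to_csv(os.path.join(out, "single_exposure.csv"), index=False)

ok = frame[frame["converged"]].sort_values("p")
print(f"{OUTCOME}: {len(matched.case_ids)} matched pairs, "
      f"{len(ok)} converged fits")
print("top associations (OR per log10 ng/mL):")
print(ok[["chemical", "or_", "ci_low", "ci_high", "p"]].head(5)
      .round(3).to_string(index=False))

top = ok.iloc[0]["chemical"]
strata = stratified_risk(vals, bundle.cohort, labels, OUTCOME, top,
                         strata="age")
srows = results_frame(strata)
srows.to_csv(os.path.join(out, f"stratified_{OUTCOME}_{top}.csv"), index=False)
if not srows.empty:
    print(f"\nage-stratified ORs for {top}:")
    print(srows[["stratum", "or_", "ci_low", "ci_high", "n_cases"]]
          .round(3).to_string(index=False))
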