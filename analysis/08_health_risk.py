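#!/usr/bin/env python
"""Guidance-value hazard quotients and the dose-risk curve.

HQ = C_serum / C_guidance with exceedance flagged at HQ > 1, followed by
a restricted-cubic-spline logistic dose-risk curve for the strongest
single-exposure association and its minimum risk dose (first sustained
OR > 1 above the anchor).
"""

import os

import numpy as np
import pandas as pd

from exposome import read_study_bundle
from exposome.associations import fit_matched, results_frame
from exposome.outcomes import classify_outcomes, match_controls
from exposome.risk import dose_risk_curve, hazard_quotients

ROOT = os.path.join(os.path.dirname(__file__), "..", "results")
bundle = read_study_bundle(os.path.join(ROOT, "bundle"))
vals = pd.read_csv(os.path.join(ROOT, "atlas", "concentrations.csv"),
                   index_col="subject_id")
labels = classify_outcomes(bundle.cohort)

guidance = pd.DataFrame(
    [{"chemical_id": c.chemical_id, "type": c.guidance_type,
      "value_ng_ml": c.guidance_value}
     for c in bundle.panel.chemicals if c.guidance_value is not None])
out = os.path.join(ROOT, "risk")
os.makedirs(out, exist_ok=True)

hq = hazard_quotients(vals, guidance)
hq["exceedance_pct"].rename_axis("chemical_id").to_csv(
    os.path.join(out, "exceedance.csv"))
worst = hq["exceedance_pct"].sort_values(ascending=False)
print(f"guidance values available for {len(guidance)} chemicals "
      f"({len(hq['skipped'])} skipped)")
print("highest exceedance rates (% of subjects with HQ > 1):")
print(worst.head(3).round(2).to_string())

OUTCOME = "hyperuricemia"
matched = match_controls(bundle.cohort, labels, OUTCOME)
assoc = results_frame(
    [fit_matched(matched, vals, bundle.cohort, labels, c)
     for c in vals.columns])
top = assoc[assoc["converged"]].sort_values("p").iloc[0]["chemical"]

ids = list(matched.case_ids) + list(matched.control_ids)
lab = labels.set_index("subject_id")
coh = bundle.cohort.set_index("subject_id")
y = (lab[OUTCOME].reindex(ids) == True).astype(float)  # noqa: E712
curve = dose_risk_curve(vals[top].reindex(ids), y, coh.loc[ids],
                        chemical=top, outcome_name=OUTCOME)
curve.grid.to_csv(os.path.join(out, f"dose_risk_{OUTCOME}_{top}.csv"),
                  index=False)
mrd = curve.minimum_risk_dose
print(f"\ndose-risk curve: {top} vs {OUTCOME}, anchor "
      f"{curve.reference_concentration:.3g} ng/mL")
print("minimum risk dose (first sustained OR>1): "
      + (f"{mrd:.3g} ng/mL" if np.isfinite(mrd) else "none within range"))
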