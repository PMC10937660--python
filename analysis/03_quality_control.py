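#!/usr/bin/env python
"""QC acceptance metrics and batch-effect assessment.

Precision (RSD < 30%), recovery (80-120%), per-curve accuracy at the
spiked levels, and the batch-effect ANOVA metric on raw QC areas versus
IS-corrected batch-quantified QC concentrations.
"""

import os

import pandas as pd

from exposome import read_study_bundle
from exposome.qc import batch_effect_metric, qc_metrics

ROOT = os.path.join(os.path.dirname(__file__), "..", "results")
bundle = read_study_bundle(os.path.join(ROOT, "bundle"))
qc_conc = pd.read_csv(os.path.join(ROOT, "atlas", "qc_concentrations.csv"))

report = qc_metrics(qc_conc)
out = os.path.join(ROOT, "qc")
os.makedirs(out, exist_ok=True)
report.precision.to_csv(os.path.join(out, "precision.csv"), index=False)
report.recovery.to_csv(os.path.join(out, "recovery.csv"), index=False)
report.summary.to_csv(os.path.join(out, "summary.csv"), index=False)

print("per-platform pass fractions:")
print(report.summary.to_string(index=False))

rows = []
for platform, table in bundle.peak_tables.items():
    prec = 2.0 if platform == "GC" else 10.0
    qc_rows = table[(table["role"] == "qc")
                    & (table["nominal_conc_ng_ml"] == prec)
                    & (table["is_id"] != "")]
    before = qc_rows.pivot_table(index="sample_id", columns="chemical_id",
                                 values="area")
    batches = qc_rows.drop_duplicates("sample_id").set_index("sample_id")["batch"]
    after = qc_conc[(qc_conc["platform"] == platform)
                    & (qc_conc["nominal"] == prec)].pivot_table(
        index="sample_id", columns="chemical_id", values="conc")
    rows.append({
        "platform": platform,
        "metric_before": batch_effect_metric(before, batches).mean(),
        "metric_after": batch_effect_metric(
            after.loc[before.index], batches).mean(),
    })
be = pd.DataFrame(rows)
be.to_csv(os.path.join(out, "batch_effect.csv"), index=False)
print("\nbatch-effect ANOVA R^2 (raw areas vs corrected concentrations):")
print(be.to_string(index=False))
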