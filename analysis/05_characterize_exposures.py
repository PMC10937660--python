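#!/usr/bin/env python
"""Exposure characterisation: detection, atlas table, structure of variation.

Detection frequencies and the high-frequency (> 50% in any region) rule,
geometric means with 95% CIs, variance partitioning over the nine
epidemiological factors, partial Spearman correlations with age, and PCA.
"""

import os

import pandas as pd

from exposome import read_study_bundle
from exposome.characterize import (concentration_table, detection_frequency,
                                   partial_spearman, pca_scores,
                                   select_high_frequency, variance_partition)
from exposome.config import EPI_FACTORS
from exposome.quantify import ConcentrationMatrix

ROOT = os.path.join(os.path.dirname(__file__), "..", "results")
bundle = read_study_bundle(os.path.join(ROOT, "bundle"))
atlas = os.path.join(ROOT, "atlas")
vals = pd.read_csv(os.path.join(atlas, "concentrations.csv"),
                   index_col="subject_id")
below = pd.read_csv(os.path.join(atlas, "below_loq.csv"),
                    index_col="subject_id").astype(bool)
batch = pd.read_csv(os.path.join(atlas, "cell_batches.csv"),
                    index_col="subject_id")
matrix = ConcentrationMatrix(values=vals, below_loq=below,
                             loq=vals * float("nan"), batch=batch, imputed=True)

coh = bundle.cohort.set_index("subject_id").reindex(vals.index)
out = os.path.join(ROOT, "characterization")
os.makedirs(out, exist_ok=True)

table = concentration_table(matrix, coh["region"])
table.rename_axis("chemical_id").to_csv(
    os.path.join(out, "concentration_table.csv"))
high = select_high_frequency(detection_frequency(matrix, coh["region"]))
print(f"high-frequency chemicals (>50% in some region): "
      f"{len(high)} of {vals.shape[1]}")

vp = variance_partition(vals, coh.reset_index(), EPI_FACTORS)
vp.to_csv(os.path.join(out, "variance_partition.csv"))
top = vp.drop(index="__joint__").sort_values("marginal", ascending=False)
print("variance explained (marginal adjusted R^2, top 3):")
print((top["marginal"] * 100).head(3).round(2).to_string())

ps = partial_spearman(vals, coh.reset_index(), "age",
                      [f for f in EPI_FACTORS if f != "age"])
ps.to_csv(os.path.join(out, "partial_spearman_age.csv"))
print(f"chemicals with q<0.05 partial correlation with age: "
      f"{int((ps['q'] < 0.05).sum())}")

scores, loadings, expl = pca_scores(vals)
scores.iloc[:, :5].rename_axis("subject_id").to_csv(
    os.path.join(out, "pca_scores.csv"))
expl.rename("explained").to_frame().to_csv(
    os.path.join(out, "pca_explained.csv"))
print(f"PC1/PC2 explain {expl.iloc[0] * 100:.1f}% / {expl.iloc[1] * 100:.1f}%")
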