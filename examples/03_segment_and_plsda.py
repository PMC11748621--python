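"""Hierarchical double k-means segmentation + per-cluster PLS-DA.

Builds a cohort in which only epithelium carries the outcome effect, segments
all images with PBM-selected k at two levels, then trains per-cluster PLS-DA
models against patient outcome. The epithelium clusters should surface with
the top patient-level AUC.
"""

import numpy as np

from chemimage.plsda import cluster_plsda_pipeline
from chemimage.preprocess import preprocess_image
from chemimage.segmentation import double_segmentation, render_false_color
from chemimage.synthetic import SynthConfig, generate_cohort

cfg = SynthConfig(n_patients=20, rows=24, cols=24, n_channels=24,
                  recurrence_rate=0.3, effect_size=0.3, noise_sd=0.02,
                  baseline_amplitude=0.05, seed=31)
cohort, images, manifest = generate_cohort(cfg)
images = [preprocess_image(im, seed=0) for im in images]

model = double_segmentation(images, subsample=2000, seed=3)
print(f"level-1 k* = {model.k1} (PBM per k: "
      f"{ {k: round(v, 3) for k, v in model.pbm_level1.items()} })")
print(f"level-2 sub-clusters: { {c: model.k2(c) for c in range(model.k1)} }")

rendered = render_false_color(images[0], model)
print(f"false-color image of {images[0].image_id}: "
      f"{rendered.max()} palette indices (+0 for substrate)")

table = cluster_plsda_pipeline(images, cohort, model, n_repeats=4, seed=1,
                               lv_max=6, cap_per_image=80)
print("\nper-cluster PLSDA (patient-level AUC over 4 repeated 60:20:20 splits):")
print(table[["cluster", "n_evaluable", "auc_mean", "auc_sd", "f1_mean"]]
      .to_string(index=False))
best = table.loc[table["auc_mean"].idxmax(), "cluster"]
print(f"\ntop cluster: {int(best)} — with the default generator this is an "
      "epithelium cluster, the tissue that carries the simulated effect.")
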