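"""Feature-level scoring of a generated stain against ground truth.

Segments nuclei and lipid droplets (with defect detection) on synthetic
scenes, summarizes per-image features, and scores a deliberately degraded
copy of the lipid channel against the original with the grouped
MAE_median / Spearman statistics.
"""

import numpy as np
from scipy import ndimage

from virtustain.evaluation import group_scores
from virtustain.features import (FeatureConfig, compute_object_features,
                                 detect_lipid_defects, image_feature_summary,
                                 segment_lipids)
from virtustain.imaging_io import Channel
from virtustain.synthetic_data import SceneSpec, generate_scene

cfg = FeatureConfig()
gt_tables, gen_tables = [], []
for i in range(6):
    _, channels, truth = generate_scene(SceneSpec(seed=40 + i))
    img = channels[Channel.LIPIDS].pixels
    # a stand-in "generated" image: slightly blurred, so small droplets and
    # defects are partially lost — the typical failure mode of a generator
    degraded = ndimage.gaussian_filter(img, 1.2)
    for image, tables in ((img, gt_tables), (degraded, gen_tables)):
        labels = segment_lipids(image, cfg)
        table = compute_object_features(labels, image, scales=cfg.granularity_scales,
                                        cfg=cfg)
        _, flags = detect_lipid_defects(image, labels, cfg)
        table.counts["count_defective"] = int(sum(flags.values()))
        tables.append(image_feature_summary(table))

scores = group_scores(gen_tables, gt_tables)
print("per-group scores of the degraded lipid channel vs ground truth:")
for group, vals in scores.groups.items():
    rho = "n/a" if vals["rho"] is None else f"{vals['rho']:.2f}"
    print(f"  {group:<10} MAE_median = {vals['mae_median']:.3f}   rho = {rho}")
print(f"  total      MAE_median = {scores.total:.3f}")
print("-> blurring costs mostly count features (lost small/defective droplets),")
print("   exactly the kind of error pixel-level MAE under-reports.")
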