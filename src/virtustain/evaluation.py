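"""Image-level and feature-level comparison statistics.

Generated stains are scored against ground truth at two levels. At the image
level: mean absolute error normalized by the median intensity of the
ground-truth image, and SSIM. At the feature level: for each per-image
feature, the median-normalized MAE

    MAE_median = mean(|y - y_hat|) / median(y)

and the Spearman rank correlation of per-image values; correlations from
multiple data splits are averaged through the Fisher (arctanh) transform.
Features are grouped into morphology, intensity and count; a group's score
is the mean of its member features' scores and the total is the mean over
groups. Model configurations are compared with a one-sided Mann-Whitney
rank test (lower score better).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skimage.metrics import structural_similarity

from .features import INTENSITY_FEATURES, MORPHOLOGY_FEATURES
from .imaging_io import ChannelImage

__all__ = [
    "GroupScores",
    "mae_median",
    "image_mae",
    "ssim",
    "fisher_average_spearman",
    "group_scores",
    "per_image_group_scores",
    "ablation_test",
]

FEATURE_GROUPS = {
    "morphology": MORPHOLOGY_FEATURES + ["granularity"],
    "intensity": INTENSITY_FEATURES,
    "count": ["count", "count_defective"],
}


def _pixels(img) -> np.ndarray:
    return np.asarray(img.pixels if isinstance(img, ChannelImage) else img, dtype=float)


def mae_median(gen_values, gt_values, signed: bool = False) -> float:
    """Mean absolute error normalized by the median of the ground truth.

    ``signed`` computes the literal signed mean difference over the median
    instead of the absolute form.
    """
    gen = np.asarray(gen_values, dtype=float)
    gt = np.asarray(gt_values, dtype=float)
    if gen.shape != gt.shape or gen.size == 0:
        raise ValueError("gen/gt must be equal-length non-empty arrays")
    med = float(np.median(gt))
    if med == 0:
        raise ValueError("median of ground-truth values is zero; MAE_median undefined")
    diff = (gt - gen) if signed else np.abs(gt - gen)
    return float(diff.mean() / med)


def image_mae(gen, gt) -> float:
    """Mean absolute pixel error normalized by the ground-truth image median."""
    g = _pixels(gen)
    t = _pixels(gt)
    if g.shape != t.shape:
        raise ValueError(f"shape mismatch: {g.shape} vs {t.shape}")
    med = float(np.median(t))
    if med == 0:
        raise ValueError("ground-truth median intensity is zero")
    return float(np.abs(g - t).mean() / med)


def ssim(gen, gt, win_size: int = 7) -> float:
    """Structural similarity with a uniform window and data range 1.0."""
    g = _pixels(gen)
    t = _pixels(gt)
    if g.shape != t.shape:
        raise ValueError(f"shape mismatch: {g.shape} vs {t.shape}")
    return float(structural_similarity(t, g, win_size=win_size, data_range=1.0,
                                       gaussian_weights=False))


def fisher_average_spearman(rhos) -> float:
    """tanh(mean(arctanh(rho_i))) — Fisher-transform averaging of correlations."""
    rhos = np.asarray(rhos, dtype=float)
    if np.any(np.abs(rhos) >= 1):
        raise ValueError("|rho| must be < 1 for the Fisher transform")
    return float(np.tanh(np.mean(np.arctanh(rhos))))


@dataclass
class GroupScores:
    """Per-group MAE_median and Spearman rho, plus per-feature detail."""

    groups: dict
    total: float
    per_feature: pd.DataFrame = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {"groups": self.groups, "total": self.total}


def group_scores(gen_tables, gt_tables, groups: dict | None = None) -> GroupScores:
    """Score matched per-image feature summaries.

    ``gen_tables`` / ``gt_tables`` are sequences of per-image feature Series
    (see ``image_feature_summary``) in matching order. Per feature the
    MAE_median over images and the Spearman correlation of per-image values
    are computed; group scores are means of member features; the total is
    the mean over groups. Features missing from the tables are excluded with
    a warning.
    """
    groups = groups or FEATURE_GROUPS
    gen_df = pd.DataFrame(list(gen_tables)).reset_index(drop=True)
    gt_df = pd.DataFrame(list(gt_tables)).reset_index(drop=True)
    if len(gen_df) != len(gt_df):
        raise ValueError("generated and ground-truth image sets differ in size")
    rows = []
    for group, feats in groups.items():
        for feat in feats:
            if feat not in gen_df.columns or feat not in gt_df.columns:
                warnings.warn(f"feature {feat!r} missing; excluded from {group} score")
                continue
            gen_v = gen_df[feat].to_numpy(dtype=float)
            gt_v = gt_df[feat].to_numpy(dtype=float)
            ok = ~(np.isnan(gen_v) | np.isnan(gt_v))
            if ok.sum() == 0:
                warnings.warn(f"feature {feat!r} has no valid image pairs; excluded")
                continue
            score = mae_median(gen_v[ok], gt_v[ok])
            if ok.sum() > 1 and np.std(gen_v[ok]) > 0 and np.std(gt_v[ok]) > 0:
                rho = float(stats.spearmanr(gen_v[ok], gt_v[ok]).statistic)
            else:
                rho = np.nan
            rows.append({"group": group, "feature": feat, "mae_median": score, "rho": rho})
    detail = pd.DataFrame(rows)
    group_summary = {}
    for group in groups:
        sub = detail[detail["group"] == group]
        if len(sub) == 0:
            continue
        group_summary[group] = {
            "mae_median": float(sub["mae_median"].mean()),
            "rho": float(sub["rho"].mean()) if sub["rho"].notna().any() else None,
        }
    total = float(np.mean([g["mae_median"] for g in group_summary.values()]))
    return GroupScores(groups=group_summary, total=total, per_feature=detail)


def per_image_group_scores(gen_tables, gt_tables, groups: dict | None = None) -> pd.DataFrame:
    """Per-image group scores for configuration comparison.

    For each image, each feature's absolute error is normalized by the
    feature's median over the ground-truth image set, then averaged within
    each group (and over groups for ``total``). Rows are images, columns are
    groups; these per-image scores feed :func:`ablation_test`.
    """
    groups = groups or FEATURE_GROUPS
    gen_df = pd.DataFrame(list(gen_tables)).reset_index(drop=True)
    gt_df = pd.DataFrame(list(gt_tables)).reset_index(drop=True)
    out = {}
    for group, feats in groups.items():
        cols = []
        for feat in feats:
            if feat not in gen_df.columns or feat not in gt_df.columns:
                continue
            med = float(gt_df[feat].median())
            if med == 0 or np.isnan(med):
                continue
            cols.append((gt_df[feat] - gen_df[feat]).abs() / med)
        if cols:
            out[group] = pd.concat(cols, axis=1).mean(axis=1)
    scores = pd.DataFrame(out)
    scores["total"] = scores.mean(axis=1)
    return scores


def ablation_test(scores_a, scores_b) -> float:
    """One-sided Mann-Whitney U p-value for "configuration a scores lower
    (better) than b". Degenerate all-tied samples return 0.5 with a warning."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both score samples must be non-empty")
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        warnings.warn("all scores tied; Mann-Whitney test is uninformative")
        return 0.5
    method = "exact" if (a.size <= 20 and b.size <= 20 and
                         np.unique(np.concatenate([a, b])).size == a.size + b.size) else "auto"
    res = stats.mannwhitneyu(a, b, alternative="less", method=method)
    return float(res.pvalue)
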