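"""Training losses for the channel-tailored virtual-staining models.

Three families:

* the nuclei (LUPI) composite — a weighted L1 reconstruction loss whose
  per-pixel weights come from the segmentation weight mask (SWM: weight
  ``eta`` where the auxiliary segmentation decoder currently misclassifies a
  pixel, 1 elsewhere), a multi-scale loss-weight module (LWM) applying the
  same weighted L1 to each intermediate decoder output against resized
  ground truth, and a binary cross-entropy term for the segmentation decoder;
* the lipid composite — L1, a forward-difference image-gradient loss, and a
  relativistic average least-squares GAN (raLSGAN) adversarial term;
* the cytoplasm model trains with plain L1.

All pixel losses support ``reduction='mean'`` (default, so learning rates are
portable across crop sizes) or ``'sum'``. Inputs may be NumPy arrays or
autograd tensors; outputs are scalar tensors (use ``float(...)`` for a plain
number). The SWM is a weighting, not an objective: it is always computed
from detached segmentation probabilities so no gradient flows through it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .imaging_io import BinaryMask
from .nn.autograd import Tensor, as_tensor, bce_with_logits

__all__ = [
    "LossConfig",
    "SegWeightMask",
    "segmentation_weight_mask",
    "weighted_l1",
    "multiscale_lwm_loss",
    "segmentation_bce",
    "nuclei_total_loss",
    "gradient_loss",
    "ralsgan_generator_loss",
    "ralsgan_discriminator_loss",
    "lipid_total_loss",
    "downscale_mean",
    "downscale_nearest",
]


@dataclass
class LossConfig:
    """Loss weights; defaults follow the published training configuration."""

    eta: float = 2.0            # SWM weight on misclassified pixels
    alpha_lwm: float = 0.1      # weight of the multi-scale LWM term
    alpha_seg: float = 0.05     # weight of the segmentation BCE term
    alpha_l1: float = 1.0       # weight of the L1 term (lipids)
    alpha_grad: float = 5.0     # weight of the gradient loss (lipids)
    alpha_adv: float = 0.01     # weight of the adversarial term (lipids)
    seg_threshold: float = 0.5  # probability threshold classifying a pixel
    reduction: str = "mean"     # 'mean' or 'sum' over pixels

    def __post_init__(self):
        if self.eta < 1:
            raise ValueError("eta must be >= 1")
        if not 0 < self.seg_threshold < 1:
            raise ValueError("seg_threshold must lie in (0, 1)")
        for name in ("alpha_lwm", "alpha_seg", "alpha_l1", "alpha_grad", "alpha_adv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.reduction not in ("mean", "sum"):
            raise ValueError("reduction must be 'mean' or 'sum'")


@dataclass
class SegWeightMask:
    """Per-pixel loss weights, each entry exactly 1 or eta."""

    weights: np.ndarray
    eta: float = 2.0

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        ok = np.isclose(self.weights, 1.0) | np.isclose(self.weights, self.eta)
        if not ok.all():
            raise ValueError("SWM entries must be exactly 1 or eta")


def _pixels(x) -> np.ndarray:
    if isinstance(x, Tensor):
        return x.data
    if hasattr(x, "pixels"):
        return np.asarray(x.pixels)
    return np.asarray(x)


def _as_loss_input(x) -> Tensor:
    if isinstance(x, Tensor):
        return x
    return Tensor(_pixels(x))


def _reduce(total: Tensor, n: int, reduction: str) -> Tensor:
    return total / n if reduction == "mean" else total


def segmentation_weight_mask(seg_prob, gt_mask, cfg: LossConfig | None = None) -> SegWeightMask:
    """SWM: weight ``eta`` where the thresholded prediction disagrees with the
    ground-truth mask, 1 where it agrees. Computed on detached values."""
    cfg = cfg or LossConfig()
    prob = _pixels(seg_prob)
    gt = _pixels(gt_mask if not isinstance(gt_mask, BinaryMask) else gt_mask.pixels)
    if prob.shape != gt.shape:
        raise ValueError(f"shape mismatch: {prob.shape} vs {gt.shape}")
    predicted = prob >= cfg.seg_threshold
    mis = predicted != (gt > 0.5)
    weights = np.where(mis, cfg.eta, 1.0)
    return SegWeightMask(weights=weights, eta=cfg.eta)


def weighted_l1(pred, gt, Z: SegWeightMask | np.ndarray | None = None,
                reduction: str = "mean") -> Tensor:
    """Sum/mean of ``Z * |pred - gt|`` over pixels (plain L1 when Z is None)."""
    pred_t = _as_loss_input(pred)
    gt_arr = _pixels(gt)
    if pred_t.shape != gt_arr.shape:
        raise ValueError(f"shape mismatch: {pred_t.shape} vs {gt_arr.shape}")
    diff = (pred_t - Tensor(gt_arr.astype(pred_t.dtype, copy=False))).abs()
    if Z is not None:
        w = Z.weights if isinstance(Z, SegWeightMask) else np.asarray(Z, dtype=float)
        if w.shape != gt_arr.shape:
            raise ValueError(f"weight mask shape {w.shape} != image shape {gt_arr.shape}")
        diff = diff * Tensor(w.astype(pred_t.dtype, copy=False))
    return _reduce(diff.sum(), pred_t.size, reduction)


def downscale_mean(img: np.ndarray, factor: int) -> np.ndarray:
    """Area-average an image by an integer factor over the last two axes."""
    h, w = img.shape[-2], img.shape[-1]
    if h % factor or w % factor:
        raise ValueError(f"{img.shape} not divisible by {factor}")
    shaped = img.reshape(*img.shape[:-2], h // factor, factor, w // factor, factor)
    return shaped.mean(axis=(-3, -1))


def downscale_nearest(img: np.ndarray, factor: int) -> np.ndarray:
    """Nearest-neighbour downscale (preserves {1, eta} weight values)."""
    h, w = img.shape[-2], img.shape[-1]
    if h % factor or w % factor:
        raise ValueError(f"{img.shape} not divisible by {factor}")
    off = factor // 2
    return img[..., off::factor, off::factor]


def multiscale_lwm_loss(scale_preds, gt, Z: SegWeightMask | np.ndarray | None = None,
                        reduction: str = "mean") -> Tensor:
    """Loss-weight module: weighted L1 of each intermediate decoder output
    against the ground truth resized to its scale, with the SWM resized
    alongside (area averaging for the image, nearest neighbour for the mask).
    """
    gt_arr = _pixels(gt)
    w_arr = None
    if Z is not None:
        w_arr = Z.weights if isinstance(Z, SegWeightMask) else np.asarray(Z, dtype=float)
    total = None
    for pred in scale_preds:
        pred_t = _as_loss_input(pred)
        ph, pw = pred_t.shape[-2], pred_t.shape[-1]
        gh, gw = gt_arr.shape[-2], gt_arr.shape[-1]
        if gh % ph or gw % pw:
            raise ValueError(f"scale output {pred_t.shape} does not evenly divide {gt_arr.shape}")
        fh, fw = gh // ph, gw // pw
        if fh != fw or (fh & (fh - 1)):
            raise ValueError(f"scale factor {fh}x{fw} is not a square power of two")
        gt_k = downscale_mean(gt_arr, fh)
        z_k = downscale_nearest(w_arr, fh) if w_arr is not None else None
        if pred_t.ndim != gt_k.ndim:  # 2-D targets against batched predictions
            gt_k = np.broadcast_to(gt_k, pred_t.shape)
            z_k = np.broadcast_to(z_k, pred_t.shape) if z_k is not None else None
        term = weighted_l1(pred_t, gt_k, z_k, reduction=reduction)
        total = term if total is None else total + term
    if total is None:
        raise ValueError("scale_preds is empty")
    return total


def segmentation_bce(seg_logits, gt_mask) -> Tensor:
    """Mean binary cross-entropy of the segmentation decoder (stable, from logits)."""
    gt = _pixels(gt_mask if not isinstance(gt_mask, BinaryMask) else gt_mask.pixels)
    logits = _as_loss_input(seg_logits)
    return bce_with_logits(logits, np.broadcast_to(gt, logits.shape))


def nuclei_total_loss(out, gt_img, gt_mask, cfg: LossConfig | None = None):
    """Composite nuclei loss: weighted L1 + alpha_lwm * LWM + alpha_seg * BCE.

    ``out`` is a generator output carrying ``image`` (full-resolution
    prediction), ``seg_logits`` and ``scale_preds``. The SWM is recomputed
    from the current segmentation output, detached. Returns ``(total,
    components)`` where components holds plain floats for logging.
    """
    cfg = cfg or LossConfig()
    gt_arr = _pixels(gt_img)
    seg_prob = 1.0 / (1.0 + np.exp(-np.clip(_pixels(out.seg_logits), -60, 60)))
    if seg_prob.ndim == 4:  # batched: SWM per sample
        z_full = np.where(
            (seg_prob >= cfg.seg_threshold) != (np.broadcast_to(gt_arr, seg_prob.shape) > 0.5),
            cfg.eta, 1.0,
        )
        swm = SegWeightMask(weights=z_full, eta=cfg.eta)
    else:
        swm = segmentation_weight_mask(seg_prob, gt_mask, cfg)
    l1_term = weighted_l1(out.image, np.broadcast_to(gt_arr, _as_loss_input(out.image).shape),
                          swm.weights, reduction=cfg.reduction)
    lwm_term = multiscale_lwm_loss(out.scale_preds, gt_arr, swm, reduction=cfg.reduction) \
        if out.scale_preds else Tensor(0.0)
    bce_term = segmentation_bce(out.seg_logits, gt_mask)
    total = l1_term + cfg.alpha_lwm * lwm_term + cfg.alpha_seg * bce_term
    components = {
        "l1_reg": float(l1_term),
        "lwm": float(lwm_term),
        "seg_bce": float(bce_term),
        "total": float(total),
    }
    return total, components


def gradient_loss(pred, gt, reduction: str = "mean") -> Tensor:
    """L1 distance between unnormalized forward-difference image gradients.

    Horizontal differences live on an H x (W-1) grid and vertical differences
    on (H-1) x W; constant offsets between pred and gt therefore cost nothing,
    while edge mismatches are penalized.
    """
    pred_t = _as_loss_input(pred)
    gt_arr = _pixels(gt)
    if pred_t.shape != gt_arr.shape:
        raise ValueError(f"shape mismatch: {pred_t.shape} vs {gt_arr.shape}")
    h, w = pred_t.shape[-2], pred_t.shape[-1]
    if h < 2 or w < 2:
        raise ValueError("gradient loss needs at least a 2x2 image")
    sl = (Ellipsis,)
    dh_pred = pred_t[sl + (slice(None), slice(1, None))] - pred_t[sl + (slice(None), slice(None, -1))]
    dv_pred = pred_t[sl + (slice(1, None), slice(None))] - pred_t[sl + (slice(None, -1), slice(None))]
    dh_gt = gt_arr[..., :, 1:] - gt_arr[..., :, :-1]
    dv_gt = gt_arr[..., 1:, :] - gt_arr[..., :-1, :]
    h_term = (dh_pred - Tensor(dh_gt)).abs().sum()
    v_term = (dv_pred - Tensor(dv_gt)).abs().sum()
    if reduction == "mean":
        n = dh_gt.size + dv_gt.size
        return (h_term + v_term) / n
    return h_term + v_term


def ralsgan_generator_loss(d_real, d_fake) -> Tensor:
    """Relativistic average least-squares GAN, generator side:
    E[(D(y) - E[D(G(x))] + 1)^2] + E[(D(G(x)) - E[D(y)] - 1)^2]."""
    return _ralsgan(d_real, d_fake, generator=True)


def ralsgan_discriminator_loss(d_real, d_fake) -> Tensor:
    """Relativistic average least-squares GAN, discriminator side:
    E[(D(y) - E[D(G(x))] - 1)^2] + E[(D(G(x)) - E[D(y)] + 1)^2]."""
    return _ralsgan(d_real, d_fake, generator=False)


def _ralsgan(d_real, d_fake, generator: bool) -> Tensor:
    dr = _as_loss_input(d_real)
    df = _as_loss_input(d_fake)
    if dr.size == 0 or df.size == 0:
        raise ValueError("empty discriminator score set")
    sign = 1.0 if generator else -1.0
    mean_df = df.mean()
    mean_dr = dr.mean()
    term_real = ((dr - mean_df + sign) ** 2).mean()
    term_fake = ((df - mean_dr - sign) ** 2).mean()
    return term_real + term_fake


def lipid_total_loss(pred, gt, d_real, d_fake, cfg: LossConfig | None = None):
    """Composite lipid loss: alpha_l1*L1 + alpha_grad*Lgrad + alpha_adv*Ladv(G).

    Returns ``(total, components)``.
    """
    cfg = cfg or LossConfig()
    l1_term = weighted_l1(pred, _pixels(gt), None, reduction=cfg.reduction)
    grad_term = gradient_loss(pred, _pixels(gt), reduction=cfg.reduction)
    adv_term = ralsgan_generator_loss(d_real, d_fake)
    total = cfg.alpha_l1 * l1_term + cfg.alpha_grad * grad_term + cfg.alpha_adv * adv_term
    components = {
        "l1": float(l1_term),
        "grad": float(grad_term),
        "adv": float(adv_term),
        "total": float(total),
    }
    return total, components
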