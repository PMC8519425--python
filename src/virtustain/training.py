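"""Channel-specific training loops.

Each fluorescence channel gets the model and loss tailored to it:

* nuclei — dual-decoder LUPI generator with the weighted-L1 + multi-scale
  LWM + segmentation BCE composite, trained with nucleus-centred crop
  sampling (probability 0.8 of cropping around a randomly chosen nucleus
  centre with a uniform offset up to 256 px, so at least one nucleus is in
  the crop) and flip + continuous-rotation augmentation;
* lipid droplets — base generator plus conditional patch discriminator,
  L1 + gradient + relativistic-average least-squares adversarial loss, with
  a generator-only warm-up before alternating generator/discriminator steps
  (1:1 after warm-up), and flip + 90-degree-rotation augmentation;
* cytoplasm — base generator with plain L1 and the lipid augmentation.

All models use AdamW with decoupled weight decay 0.01 and constant learning
rates; the best checkpoint is the one with the lowest validation loss, where
the validation loss is the composite loss without adversarial terms (an
adversarial score is not comparable across steps). A fixed seed fixes the
crop/augmentation stream and, on CPU, the entire loss history.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .imaging_io import BinaryMask, Channel
from .losses import LossConfig, lipid_total_loss, nuclei_total_loss, weighted_l1, gradient_loss
from .networks import (
    DenseUNetSpec,
    DiscriminatorSpec,
    DenseUNet,
    LupiDenseUNet,
    PatchDiscriminator,
    build_dense_unet,
    build_lupi_unet,
    build_patch_discriminator,
)
from .nn import AdamW
from .nn.autograd import Tensor
from .synthetic_data import SceneExample

__all__ = [
    "TrainConfig",
    "TrainExample",
    "NucleiCenters",
    "TrainingDiverged",
    "extract_nuclei_centers",
    "sample_crop",
    "augment",
    "train_channel",
    "TrainResult",
    "save_checkpoint",
    "load_checkpoint",
    "validation_loss",
    "segmentation_accuracy",
]

# published per-channel settings: iterations, batch size, generator lr
_PAPER_SCHEDULES = {
    Channel.NUCLEI: dict(iterations=51_400, batch_size=12, lr=1e-3),
    Channel.LIPIDS: dict(iterations=30_000, batch_size=4, lr=1e-4),
    Channel.CYTOPLASM: dict(iterations=75_000, batch_size=4, lr=1e-4),
}


class TrainingDiverged(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass
class NucleiCenters:
    """Rounded centroids of the nuclei in one image."""

    centers: list


@dataclass
class TrainExample:
    """One registered training pair (stack, target channel, optional mask)."""

    stack: np.ndarray
    target: np.ndarray
    mask: np.ndarray | None = None
    centers: list | None = None
    well: str = ""

    @classmethod
    def from_scene(cls, scene: SceneExample, channel: Channel) -> "TrainExample":
        channel = Channel(channel)
        mask = scene.truth.nuclei_mask.pixels if channel == Channel.NUCLEI else None
        return cls(
            stack=scene.stack.planes,
            target=scene.channels[channel].pixels,
            mask=mask,
            centers=list(scene.truth.nuclei_centers),
            well=scene.well,
        )


@dataclass
class TrainConfig:
    """Training hyperparameters; defaults mirror the published configuration."""

    channel: Channel = Channel.NUCLEI
    iterations: int = 51_400
    batch_size: int = 12
    lr: float = 1e-3
    lr_discriminator: float = 1e-5
    warmup_generator_iters: int = 1500
    weight_decay: float = 0.01
    crop: int = 512
    p_center_crop: float = 0.8
    max_center_offset: int = 256
    seed: int = 0
    val_interval: int = 50
    model: DenseUNetSpec = field(default_factory=lambda: DenseUNetSpec(n_blocks_per_path=5))
    discriminator: DiscriminatorSpec = field(default_factory=DiscriminatorSpec)
    loss: LossConfig = field(default_factory=LossConfig)
    # model/loss variant switches; None resolves from the channel (used by the
    # ablation runner to train e.g. a plain-L1 nuclei model)
    lupi: bool | None = None
    adversarial: bool | None = None

    def __post_init__(self):
        self.channel = Channel(self.channel)
        if self.lupi is None:
            self.lupi = self.channel == Channel.NUCLEI
        if self.adversarial is None:
            self.adversarial = self.channel == Channel.LIPIDS
        if not 0 <= self.p_center_crop <= 1:
            raise ValueError("p_center_crop must lie in [0, 1]")
        if self.crop % 2 ** self.model.n_blocks_per_path:
            raise ValueError("crop must be divisible by 2^model depth")
        if self.adversarial and self.iterations <= self.warmup_generator_iters:
            raise ValueError("iterations must exceed the generator warm-up")

    @classmethod
    def for_channel(cls, channel: Channel | str, **overrides) -> "TrainConfig":
        channel = Channel(channel)
        depth = 5 if channel == Channel.NUCLEI else 4
        kwargs = dict(_PAPER_SCHEDULES[channel])
        kwargs.update(channel=channel, model=DenseUNetSpec(n_blocks_per_path=depth))
        kwargs.update(overrides)
        return cls(**kwargs)

    @classmethod
    def tiny(cls, channel: Channel | str, seed: int = 0, iterations: int = 300,
             **overrides) -> "TrainConfig":
        """Desk-scale profile: depth-2 generator, growth 4, 64 px crops."""
        channel = Channel(channel)
        model = DenseUNetSpec(n_blocks_per_path=2, layers_per_block=2, growth_rate=4,
                              init_features=8, dropout_rate=0.1)
        disc = DiscriminatorSpec(in_planes=8, base_features=8, n_strided=2)
        kwargs = dict(
            channel=channel, iterations=iterations, batch_size=4,
            lr=1e-3 if channel == Channel.NUCLEI else 3e-4,
            lr_discriminator=3e-5, warmup_generator_iters=100,
            crop=64, max_center_offset=24, seed=seed, val_interval=25,
            model=model, discriminator=disc,
        )
        kwargs.update(overrides)
        return cls(**kwargs)


def extract_nuclei_centers(mask) -> NucleiCenters:
    """One rounded centroid per connected component of a binary mask."""
    pix = mask.pixels if isinstance(mask, BinaryMask) else np.asarray(mask)
    labels, n = ndimage.label(pix > 0)
    if n == 0:
        return NucleiCenters(centers=[])
    coms = ndimage.center_of_mass(pix > 0, labels, index=range(1, n + 1))
    return NucleiCenters(centers=[(int(round(r)), int(round(c))) for r, c in coms])


def sample_crop(example: TrainExample, centers, cfg: TrainConfig,
                rng: np.random.Generator) -> TrainExample:
    """Crop one training window; the identical window is applied to the
    stack, the target and (if present) the mask.

    With probability ``p_center_crop`` the window centre is a uniformly
    chosen nucleus centre plus a uniform offset in
    ``[-max_center_offset, max_center_offset]^2``; otherwise the window is
    uniform over valid positions. Windows are clipped to the image bounds.
    """
    crop = cfg.crop
    h, w = example.target.shape
    if h < crop or w < crop:
        raise ValueError(f"image {h}x{w} smaller than crop {crop}")
    center_list = centers.centers if isinstance(centers, NucleiCenters) else (centers or [])
    if center_list and rng.random() < cfg.p_center_crop:
        cr, cc = center_list[rng.integers(len(center_list))]
        off = cfg.max_center_offset
        cr += int(rng.integers(-off, off + 1))
        cc += int(rng.integers(-off, off + 1))
        top = int(np.clip(cr - crop // 2, 0, h - crop))
        left = int(np.clip(cc - crop // 2, 0, w - crop))
    else:
        top = int(rng.integers(0, h - crop + 1))
        left = int(rng.integers(0, w - crop + 1))
    sl = (slice(top, top + crop), slice(left, left + crop))
    return TrainExample(
        stack=example.stack[:, sl[0], sl[1]],
        target=example.target[sl],
        mask=None if example.mask is None else example.mask[sl],
        centers=None,
        well=example.well,
    )


def augment(example: TrainExample, rng: np.random.Generator,
            mode: str = "nuclei") -> TrainExample:
    """Random flips for all channels; plus continuous rotation up to +/-180
    degrees (bilinear, reflect padding; mask nearest-neighbour) in ``nuclei``
    mode, or random multiples of 90 degrees in ``lipids`` mode. The stack,
    target and mask receive the identical transform."""
    stack, target, mask = example.stack, example.target, example.mask
    if rng.random() < 0.5:
        stack, target = stack[:, :, ::-1], target[:, ::-1]
        mask = mask[:, ::-1] if mask is not None else None
    if rng.random() < 0.5:
        stack, target = stack[:, ::-1, :], target[::-1, :]
        mask = mask[::-1, :] if mask is not None else None
    if mode == "nuclei":
        angle = float(rng.uniform(-180.0, 180.0))
        if abs(angle) > 1e-9:
            stack = np.stack([
                ndimage.rotate(p, angle, reshape=False, order=1, mode="reflect")
                for p in stack
            ])
            target = ndimage.rotate(target, angle, reshape=False, order=1, mode="reflect")
            if mask is not None:
                mask = ndimage.rotate(mask, angle, reshape=False, order=0, mode="reflect")
    else:
        k = int(rng.integers(4))
        if k:
            stack = np.rot90(stack, k, axes=(1, 2))
            target = np.rot90(target, k)
            mask = np.rot90(mask, k) if mask is not None else None
    return TrainExample(stack=np.ascontiguousarray(stack),
                        target=np.ascontiguousarray(np.clip(target, 0, 1)),
                        mask=None if mask is None else np.ascontiguousarray(mask),
                        well=example.well)


@dataclass
class TrainResult:
    """Outcome of a training run."""

    model: DenseUNet
    discriminator: PatchDiscriminator | None
    history: pd.DataFrame
    best_val_loss: float
    best_step: int
    best_state: dict


def _center_crop(example: TrainExample, crop: int) -> TrainExample:
    h, w = example.target.shape
    top, left = (h - crop) // 2, (w - crop) // 2
    sl = (slice(top, top + crop), slice(left, left + crop))
    return TrainExample(stack=example.stack[:, sl[0], sl[1]], target=example.target[sl],
                        mask=None if example.mask is None else example.mask[sl])


def _batch(examples, cfg: TrainConfig, rng) -> tuple:
    mode = "nuclei" if cfg.channel == Channel.NUCLEI else "lipids"
    stacks, targets, masks = [], [], []
    for _ in range(cfg.batch_size):
        ex = examples[rng.integers(len(examples))]
        centers = ex.centers if cfg.channel == Channel.NUCLEI else None
        cropped = sample_crop(ex, centers, cfg, rng)
        aug = augment(cropped, rng, mode=mode)
        stacks.append(aug.stack)
        targets.append(aug.target[None])
        if aug.mask is not None:
            masks.append(aug.mask[None])
    stack_b = np.stack(stacks).astype(np.float32)
    target_b = np.stack(targets).astype(np.float32)
    mask_b = np.stack(masks).astype(np.float32) if masks else None
    return stack_b, target_b, mask_b


def validation_loss(model, cfg: TrainConfig, val_examples) -> float:
    """Composite validation loss without adversarial terms, on fixed centre
    crops, in eval mode."""
    was_training = model.training
    model.eval()
    losses = []
    try:
        for ex in val_examples:
            cc = _center_crop(ex, cfg.crop)
            stack = cc.stack[None].astype(np.float32)
            target = cc.target[None, None].astype(np.float32)
            if cfg.lupi:
                out = model(stack)
                total, _ = nuclei_total_loss(out, target, cc.mask[None, None].astype(np.float32),
                                             cfg.loss)
                losses.append(float(total))
            elif cfg.channel == Channel.LIPIDS:
                pred = model(stack)
                val = cfg.loss.alpha_l1 * float(weighted_l1(pred, target, reduction=cfg.loss.reduction))
                val += cfg.loss.alpha_grad * float(
                    gradient_loss(pred, target, reduction=cfg.loss.reduction))
                losses.append(val)
            else:
                pred = model(stack)
                losses.append(float(weighted_l1(pred, target, reduction=cfg.loss.reduction)))
    finally:
        model.train(was_training)
    return float(np.mean(losses))


def segmentation_accuracy(model: LupiDenseUNet, cfg: TrainConfig, examples,
                          threshold: float = 0.5) -> float:
    """Mean pixel accuracy of the LUPI segmentation decoder on centre crops."""
    examples = [TrainExample.from_scene(ex, cfg.channel)
                if isinstance(ex, SceneExample) else ex for ex in examples]
    accs = []
    for ex in examples:
        cc = _center_crop(ex, cfg.crop)
        prob = model.predict_segmentation(cc.stack.astype(np.float32))
        pred = prob >= threshold
        accs.append(float((pred == (cc.mask > 0.5)).mean()))
    return float(np.mean(accs))


def train_channel(cfg: TrainConfig, train_examples, val_examples) -> TrainResult:
    """Run the channel-appropriate training loop.

    ``train_examples`` / ``val_examples`` are sequences of
    :class:`TrainExample` (or :class:`SceneExample`, converted internally).
    Returns the trained model, the loss history (one record per step and
    component) and the best-validation checkpoint state.
    """
    train_examples = [TrainExample.from_scene(ex, cfg.channel)
                      if isinstance(ex, SceneExample) else ex for ex in train_examples]
    val_examples = [TrainExample.from_scene(ex, cfg.channel)
                    if isinstance(ex, SceneExample) else ex for ex in val_examples]
    if not train_examples or not val_examples:
        raise ValueError("need at least one training and one validation example")
    rng = np.random.default_rng(cfg.seed)
    is_nuclei = bool(cfg.lupi)
    is_gan = bool(cfg.adversarial)
    is_l1_grad = (not is_nuclei) and (not is_gan) and cfg.channel == Channel.LIPIDS
    if is_nuclei:
        model = build_lupi_unet(cfg.model, seed=cfg.seed)
    else:
        model = build_dense_unet(cfg.model, seed=cfg.seed)
    opt = AdamW(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    disc = d_opt = None
    if is_gan:
        disc_spec = DiscriminatorSpec(in_planes=cfg.model.in_planes + 1,
                                      base_features=cfg.discriminator.base_features,
                                      n_strided=cfg.discriminator.n_strided)
        disc = build_patch_discriminator(disc_spec, seed=cfg.seed + 1)
        d_opt = AdamW(disc.parameters(), lr=cfg.lr_discriminator,
                      weight_decay=cfg.weight_decay)
    records = []
    best_val, best_step, best_state = np.inf, -1, None

    def log(step, component, value):
        records.append({"step": step, "channel": cfg.channel.value,
                        "component": component, "value": float(value)})

    for step in range(cfg.iterations):
        stack_b, target_b, mask_b = _batch(train_examples, cfg, rng)
        model.zero_grad()
        if is_nuclei:
            out = model(stack_b)
            total, comps = nuclei_total_loss(out, target_b, mask_b, cfg.loss)
            for name, val in comps.items():
                log(step, name, val)
        elif is_gan or is_l1_grad:
            pred = model(stack_b)
            in_warmup = is_l1_grad or step < cfg.warmup_generator_iters
            if in_warmup:
                l1 = weighted_l1(pred, target_b, reduction=cfg.loss.reduction)
                grad = gradient_loss(pred, target_b, reduction=cfg.loss.reduction)
                total = cfg.loss.alpha_l1 * l1 + cfg.loss.alpha_grad * grad
                comps = {"l1": float(l1), "grad": float(grad), "total": float(total)}
            else:
                d_real_const = Tensor(disc(stack_b, Tensor(target_b[:, 0])).data)
                d_fake = disc(stack_b, pred.reshape(pred.shape[0], *pred.shape[2:]))
                total, comps = lipid_total_loss(pred, target_b, d_real_const, d_fake, cfg.loss)
            for name, val in comps.items():
                log(step, name, val)
        else:
            pred = model(stack_b)
            total = weighted_l1(pred, target_b, reduction=cfg.loss.reduction)
            log(step, "l1", float(total))
            log(step, "total", float(total))
        if not np.isfinite(float(total)):
            raise TrainingDiverged(f"non-finite loss at step {step}: {float(total)}")
        total.backward()
        opt.step()
        if is_gan and step >= cfg.warmup_generator_iters:
            disc.zero_grad()
            model.zero_grad()
            fake_const = Tensor(pred.data[:, 0])
            from .losses import ralsgan_discriminator_loss

            d_real = disc(stack_b, Tensor(target_b[:, 0]))
            d_fake = disc(stack_b, fake_const)
            d_loss = ralsgan_discriminator_loss(d_real, d_fake)
            if not np.isfinite(float(d_loss)):
                raise TrainingDiverged(f"non-finite discriminator loss at step {step}")
            d_loss.backward()
            d_opt.step()
            log(step, "d_loss", float(d_loss))
        if (step + 1) % cfg.val_interval == 0 or step == cfg.iterations - 1:
            vloss = validation_loss(model, cfg, val_examples)
            log(step, "val_loss", vloss)
            if vloss < best_val:
                best_val, best_step = vloss, step
                best_state = model.state_dict()
    history = pd.DataFrame(records)
    return TrainResult(model=model, discriminator=disc, history=history,
                       best_val_loss=float(best_val), best_step=best_step,
                       best_state=best_state)


# ------------------------------------------------------------- checkpoints
def save_checkpoint(path, model, cfg: TrainConfig, step: int, val_loss: float,
                    state: dict | None = None) -> None:
    """Serialize architecture spec, weights and training step to one .npz."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "channel": cfg.channel.value,
        "spec": asdict(cfg.model),
        "step": step,
        "val_loss": val_loss,
        "seed": cfg.seed,
    }
    state = state if state is not None else model.state_dict()
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **state)


def load_checkpoint(path):
    """Rebuild the generator recorded in a checkpoint; returns (model, meta)."""
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    spec = DenseUNetSpec(**meta["spec"])
    channel = Channel(meta["channel"])
    model = build_lupi_unet(spec, seed=meta.get("seed", 0)) if channel == Channel.NUCLEI \
        else build_dense_unet(spec, seed=meta.get("seed", 0))
    model.load_state_dict(state)
    model.eval()
    return model, meta
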