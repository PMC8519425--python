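"""Generator and discriminator architectures.

The base generator is a dense U-Net: an encoder/decoder with concatenating
skip connections where every block is a dense block (batch-norm -> ReLU ->
3x3 convolution -> dropout quartets, densely connected within the block, plus
a skip over the block on the contracting path). Transitions down are spatial
max pooling; transitions up are pixel-shuffle followed by a fixed 2x2
averaging blur to suppress checkerboard artifacts.

The LUPI (learning-using-privileged-information) variant used for the nuclei
channel shares one encoder and carries two decoders: an outer segmentation
decoder (the privileged-information path) and an inner image decoder. The
segmentation decoder's features are propagated to the image decoder by
pixel-wise summation of the corresponding intermediate blocks, and every
intermediate image-decoder block emits a prediction through a 1x1
convolution, providing the per-scale outputs consumed by the multi-scale
loss-weight module.

The discriminator is a conditional patch critic: it sees the bright-field
stack concatenated with a real or generated fluorescence image and emits a
spatial map of least-squares scores (no final sigmoid), each with a limited
receptive field.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import nn
from .nn.autograd import Tensor, concat, pixel_shuffle

__all__ = [
    "DenseUNetSpec",
    "DiscriminatorSpec",
    "GeneratorOutput",
    "DenseUNet",
    "LupiDenseUNet",
    "PatchDiscriminator",
    "build_dense_unet",
    "build_lupi_unet",
    "build_patch_discriminator",
]


@dataclass
class DenseUNetSpec:
    """Architecture hyperparameters.

    ``n_blocks_per_path`` is 4 for the lipid/cytoplasm models and 5 for the
    nuclei model; the growth rate defaults to 12 and the dropout rate to 0.2.
    """

    n_blocks_per_path: int = 4
    layers_per_block: int = 4
    growth_rate: int = 12
    dropout_rate: float = 0.2
    in_planes: int = 7
    out_planes: int = 1
    init_features: int = 48
    kernel_size: int = 3

    def __post_init__(self):
        if self.n_blocks_per_path < 1:
            raise ValueError("n_blocks_per_path must be >= 1")
        if self.growth_rate < 1:
            raise ValueError("growth_rate must be >= 1")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")


@dataclass
class DiscriminatorSpec:
    """Patch-discriminator hyperparameters (conditional: stack planes + 1)."""

    in_planes: int = 8
    base_features: int = 64
    n_strided: int = 3

    def __post_init__(self):
        if self.n_strided < 1:
            raise ValueError("n_strided must be >= 1")

    @property
    def receptive_field_px(self) -> int:
        # kernel 4 throughout: n_strided stride-2 convs, one stride-1 conv,
        # and the final 1-channel stride-1 conv
        rf = 1
        for _ in range(2):
            rf = (rf - 1) * 1 + 4
        for _ in range(self.n_strided):
            rf = (rf - 1) * 2 + 4
        return rf


@dataclass
class GeneratorOutput:
    """Forward-pass products of a generator.

    ``image`` is the full-resolution prediction; ``seg_logits`` and
    ``scale_preds`` (ordered coarse to fine) are present only for the LUPI
    variant.
    """

    image: Tensor
    seg_logits: Optional[Tensor] = None
    scale_preds: list = field(default_factory=list)


class _DenseLayer(nn.Module):
    """One BN -> ReLU -> conv -> dropout quartet."""

    def __init__(self, in_ch: int, growth: int, kernel: int, p_drop: float, rng):
        super().__init__()
        self.bn = nn.BatchNorm2d(in_ch)
        self.conv = nn.Conv2d(in_ch, growth, kernel, rng)
        self.drop = nn.Dropout(p_drop, rng)

    def forward(self, x):
        return self.drop(self.conv(self.bn(x).relu()))


class _DenseBlock(nn.Module):
    """Densely connected stack of quartets.

    Layer l receives the concatenation of the block input and all earlier
    layer outputs, so feature width grows by the growth rate per layer. With
    ``keep_input`` the block output also concatenates its input (the skip
    over the block used on the contracting path); otherwise only the newly
    produced features are returned (upsampling path).
    """

    def __init__(self, in_ch: int, n_layers: int, growth: int, kernel: int,
                 p_drop: float, rng, keep_input: bool):
        super().__init__()
        self.keep_input = keep_input
        self.layers = nn.ModuleList()
        ch = in_ch
        for _ in range(n_layers):
            self.layers.append(_DenseLayer(ch, growth, kernel, p_drop, rng))
            ch += growth
        self.out_channels = ch if keep_input else n_layers * growth

    def forward(self, x):
        feats = [x]
        for layer in self.layers:
            inp = feats[0] if len(feats) == 1 else concat(feats, axis=1)
            feats.append(layer(inp))
        if self.keep_input:
            return concat(feats, axis=1)
        new = feats[1:]
        return new[0] if len(new) == 1 else concat(new, axis=1)


class _TransitionUp(nn.Module):
    """Pixel-shuffle x2 upsampling followed by a fixed 2x2 blur."""

    def __init__(self, in_ch: int, out_ch: int, rng):
        super().__init__()
        self.conv = nn.Conv2d(in_ch, out_ch * 4, 3, rng)
        self.blur = nn.Blur2d()
        self.out_channels = out_ch

    def forward(self, x):
        return self.blur(pixel_shuffle(self.conv(x), 2))


class _Decoder(nn.Module):
    """One upsampling path of dense blocks fed by encoder skips."""

    def __init__(self, bottleneck_ch: int, skip_channels: list[int], spec: DenseUNetSpec, rng):
        super().__init__()
        m, g = spec.layers_per_block, spec.growth_rate
        self.ups = nn.ModuleList()
        self.blocks = nn.ModuleList()
        ch = bottleneck_ch
        for skip_ch in reversed(skip_channels):
            self.ups.append(_TransitionUp(ch, ch, rng))
            block = _DenseBlock(ch + skip_ch, m, g, spec.kernel_size, spec.dropout_rate, rng,
                                keep_input=False)
            self.blocks.append(block)
            ch = block.out_channels
        self.out_channels = ch


class DenseUNet(nn.Module):
    """Base generator mapping (n_planes, H, W) stacks to one channel image."""

    def __init__(self, spec: DenseUNetSpec, seed: int = 0):
        super().__init__()
        self.spec = spec
        rng = np.random.default_rng(seed)
        m, g, k = spec.layers_per_block, spec.growth_rate, spec.kernel_size
        self.stem = nn.Conv2d(spec.in_planes, spec.init_features, k, rng)
        self.enc_blocks = nn.ModuleList()
        self.pool = nn.MaxPool2d(2)
        ch = spec.init_features
        self.skip_channels = []
        for _ in range(spec.n_blocks_per_path):
            block = _DenseBlock(ch, m, g, k, spec.dropout_rate, rng, keep_input=True)
            self.enc_blocks.append(block)
            ch = block.out_channels
            self.skip_channels.append(ch)
        self.bottleneck = _DenseBlock(ch, m, g, k, spec.dropout_rate, rng, keep_input=False)
        self.decoder = _Decoder(self.bottleneck.out_channels, self.skip_channels, spec, rng)
        self.head = nn.Conv2d(self.decoder.out_channels, spec.out_planes, 1, rng)

    # ------------------------------------------------------------------
    def _check_input(self, x) -> Tensor:
        t = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))
        if t.ndim == 3:
            t = t.reshape(1, *t.shape)
        if t.shape[1] != self.spec.in_planes:
            raise ValueError(f"expected {self.spec.in_planes} input planes, got {t.shape[1]}")
        div = 2 ** self.spec.n_blocks_per_path
        if t.shape[2] % div or t.shape[3] % div:
            raise ValueError(f"H and W must be divisible by {div}, got {t.shape[2:]}")
        return t

    def _encode(self, t):
        h = self.stem(t)
        skips = []
        for block in self.enc_blocks:
            h = block(h)
            skips.append(h)
            h = self.pool(h)
        return self.bottleneck(h), skips

    def forward(self, x) -> Tensor:
        t = self._check_input(x)
        h, skips = self._encode(t)
        for up, block, skip in zip(self.decoder.ups, self.decoder.blocks, reversed(skips)):
            h = block(concat([up(h), skip], axis=1))
        return self.head(h).sigmoid()

    def predict(self, stack) -> np.ndarray:
        """Eval-mode numpy forward on one (n_planes, H, W) stack."""
        was_training = self.training
        self.eval()
        try:
            out = self.forward(np.asarray(stack, dtype=np.float32))
        finally:
            self.train(was_training)
        return out.data[0, 0]


class LupiDenseUNet(DenseUNet):
    """Dual-decoder LUPI generator for the nuclei channel.

    The segmentation decoder (privileged path) runs alongside the image
    decoder; its block outputs are added pixel-wise into the image decoder's
    block outputs. Each intermediate image-decoder block additionally emits a
    prediction through a 1x1 convolution, giving ``n_blocks_per_path - 1``
    per-scale outputs (coarse to fine) for the multi-scale loss.
    """

    def __init__(self, spec: DenseUNetSpec, seed: int = 0):
        super().__init__(spec, seed)
        rng = np.random.default_rng(seed + 1)
        self.seg_decoder = _Decoder(self.bottleneck.out_channels, self.skip_channels,
                                    self.spec, rng)
        self.seg_head = nn.Conv2d(self.seg_decoder.out_channels, 1, 1, rng)
        self.scale_heads = nn.ModuleList(
            nn.Conv2d(self.decoder.blocks[i].out_channels, 1, 1, rng)
            for i in range(self.spec.n_blocks_per_path - 1)
        )

    def forward(self, x, use_seg: bool = True) -> GeneratorOutput:
        t = self._check_input(x)
        h, skips = self._encode(t)
        h_img, h_seg = h, h
        scale_preds = []
        n_blocks = self.spec.n_blocks_per_path
        for i in range(n_blocks):
            skip = skips[n_blocks - 1 - i]
            h_seg = self.seg_decoder.blocks[i](concat([self.seg_decoder.ups[i](h_seg), skip], axis=1))
            h_img = self.decoder.blocks[i](concat([self.decoder.ups[i](h_img), skip], axis=1))
            if use_seg:
                h_img = h_img + h_seg  # privileged-information summation
            if i < n_blocks - 1:
                scale_preds.append(self.scale_heads[i](h_img).sigmoid())
        image = self.head(h_img).sigmoid()
        seg_logits = self.seg_head(h_seg)
        return GeneratorOutput(image=image, seg_logits=seg_logits, scale_preds=scale_preds)

    def predict(self, stack) -> np.ndarray:
        was_training = self.training
        self.eval()
        try:
            out = self.forward(np.asarray(stack, dtype=np.float32))
        finally:
            self.train(was_training)
        return out.image.data[0, 0]

    def predict_segmentation(self, stack) -> np.ndarray:
        """Eval-mode segmentation probability map for one stack."""
        was_training = self.training
        self.eval()
        try:
            out = self.forward(np.asarray(stack, dtype=np.float32))
        finally:
            self.train(was_training)
        z = out.seg_logits.data[0, 0]
        return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


class PatchDiscriminator(nn.Module):
    """Conditional least-squares patch critic.

    Input is the bright-field stack concatenated with one fluorescence image
    (``in_planes = stack planes + 1``); output is a 2-D score map with no
    final sigmoid.
    """

    def __init__(self, spec: DiscriminatorSpec, seed: int = 0):
        super().__init__()
        self.spec = spec
        rng = np.random.default_rng(seed)
        layers = []
        ch = spec.in_planes
        feats = spec.base_features
        for i in range(spec.n_strided):
            layers.append(nn.Conv2d(ch, feats, 4, rng, stride=2, padding=1))
            if i > 0:
                layers.append(nn.BatchNorm2d(feats))
            layers.append(nn.LeakyReLU(0.2))
            ch, feats = feats, feats * 2
        layers.append(nn.Conv2d(ch, feats, 4, rng, stride=1, padding=1))
        layers.append(nn.BatchNorm2d(feats))
        layers.append(nn.LeakyReLU(0.2))
        layers.append(nn.Conv2d(feats, 1, 4, rng, stride=1, padding=1))
        self.net = nn.Sequential(*layers)

    def forward(self, stack, image=None) -> Tensor:
        if image is not None:
            stack_t = stack if isinstance(stack, Tensor) else Tensor(np.asarray(stack, dtype=np.float32))
            img_t = image if isinstance(image, Tensor) else Tensor(np.asarray(image, dtype=np.float32))
            if stack_t.ndim == 3:
                stack_t = stack_t.reshape(1, *stack_t.shape)
            if img_t.ndim == 2:
                img_t = img_t.reshape(1, 1, *img_t.shape)
            elif img_t.ndim == 3:
                img_t = img_t.reshape(img_t.shape[0], 1, *img_t.shape[1:])
            x = concat([stack_t, img_t], axis=1)
        else:
            x = stack if isinstance(stack, Tensor) else Tensor(np.asarray(stack, dtype=np.float32))
            if x.ndim == 3:
                x = x.reshape(1, *x.shape)
        if x.shape[1] != self.spec.in_planes:
            raise ValueError(f"expected {self.spec.in_planes} channels, got {x.shape[1]}")
        return self.net(x)


def build_dense_unet(spec: DenseUNetSpec, seed: int = 0) -> DenseUNet:
    """Construct the base dense U-Net generator (seeded, deterministic init)."""
    return DenseUNet(spec, seed=seed)


def build_lupi_unet(spec: DenseUNetSpec, seed: int = 0) -> LupiDenseUNet:
    """Construct the dual-decoder LUPI generator."""
    return LupiDenseUNet(spec, seed=seed)


def build_patch_discriminator(spec: DiscriminatorSpec, seed: int = 0) -> PatchDiscriminator:
    """Construct the conditional patch discriminator."""
    return PatchDiscriminator(spec, seed=seed)
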