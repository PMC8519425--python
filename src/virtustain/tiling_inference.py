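"""Pyramidal weighted tiled inference.

Full microscopy frames (~2156 x 2556 px) exceed what a generator can process
in one pass, so inference runs on overlapping tiles (default 512 x 512 with a
256 x 256 stride). Each tile's output is multiplied by a pyramidal weight
mask — maximal at the tile centre and decaying linearly towards the edges —
and the weighted outputs are summed and normalized by the accumulated weight,
so every output pixel is a convex combination of the tile outputs covering
it. Borders are reflect-padded so each pixel is covered by at least one full
tile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imaging_io import BrightfieldStack, Channel, ChannelImage

__all__ = ["TileScheme", "pyramid_weight_mask", "tiled_apply"]


@dataclass
class TileScheme:
    """Tile size, stride and border policy for overlapped inference."""

    tile: tuple[int, int] = (512, 512)
    stride: tuple[int, int] = (256, 256)
    pad_mode: str = "reflect"

    def __post_init__(self):
        self.tile = tuple(int(t) for t in self.tile)
        self.stride = tuple(int(s) for s in self.stride)
        if any(s <= 0 for s in self.stride) or any(t <= 0 for t in self.tile):
            raise ValueError("tile and stride must be positive")
        if any(s > t for s, t in zip(self.stride, self.tile)):
            raise ValueError("stride must not exceed tile size")
        if self.pad_mode not in ("reflect", "zero"):
            raise ValueError("pad_mode must be 'reflect' or 'zero'")


def pyramid_weight_mask(tile: tuple[int, int]) -> np.ndarray:
    """Separable pyramid: weight(i,j) = (1 - |i-ci|/(ci+1)) * (1 - |j-cj|/(cj+1)).

    Strictly positive everywhere, maximal at the centre, non-increasing along
    every row and column away from the centre.
    """
    th, tw = int(tile[0]), int(tile[1])
    if th < 2 or tw < 2:
        raise ValueError("tile must be at least 2x2")

    def ramp(n: int) -> np.ndarray:
        c = (n - 1) / 2.0
        idx = np.arange(n, dtype=float)
        return 1.0 - np.abs(idx - c) / (c + 1.0)

    return np.outer(ramp(th), ramp(tw))


def _pad_amounts(size: int, tile: int, stride: int) -> int:
    if size <= tile:
        return tile - size
    n_steps = -(-(size - tile) // stride)  # ceil
    return tile + n_steps * stride - size


def tiled_apply(operator, stack, scheme: TileScheme | None = None,
                weight_mask: np.ndarray | None = None,
                channel: Channel | str | None = None):
    """Apply ``operator`` (a callable mapping a (n_planes, th, tw) array to a
    (th, tw) array) over the stack in overlapping tiles and blend the
    results with pyramidal weights.

    The output has the same height/width as the input planes; every output
    pixel is the weight-normalized average of the covering tile outputs.
    Returns a raw array, or a clipped :class:`ChannelImage` when ``channel``
    is given.
    """
    scheme = scheme or TileScheme()
    planes = stack.planes if isinstance(stack, BrightfieldStack) else np.asarray(stack)
    if planes.ndim == 2:
        planes = planes[None]
    _, h, w = planes.shape
    th, tw = scheme.tile
    sh, sw = scheme.stride
    ph, pw = _pad_amounts(h, th, sh), _pad_amounts(w, tw, sw)
    if scheme.pad_mode == "reflect":
        padded = np.pad(planes, ((0, 0), (0, ph), (0, pw)), mode="reflect")
    else:
        padded = np.pad(planes, ((0, 0), (0, ph), (0, pw)))
    hp, wp = padded.shape[1:]
    weights = pyramid_weight_mask((th, tw)) if weight_mask is None else np.asarray(weight_mask, dtype=float)
    if weights.shape != (th, tw):
        raise ValueError(f"weight mask shape {weights.shape} != tile {scheme.tile}")
    if weights.min() <= 0:
        raise ValueError("weight mask must be strictly positive")
    acc = np.zeros((hp, wp), dtype=np.float64)
    acc_w = np.zeros((hp, wp), dtype=np.float64)
    for top in range(0, hp - th + 1, sh):
        for left in range(0, wp - tw + 1, sw):
            tile_in = padded[:, top : top + th, left : left + tw]
            out = np.asarray(operator(tile_in))
            if out.ndim != 2 or out.shape != (th, tw):
                raise ValueError(f"operator returned shape {out.shape}, expected {(th, tw)}")
            acc[top : top + th, left : left + tw] += weights * out
            acc_w[top : top + th, left : left + tw] += weights
    if acc_w.min() <= 0:
        raise RuntimeError("tiling left uncovered pixels")  # unreachable by construction
    blended = (acc / acc_w)[:h, :w]
    if channel is not None:
        return ChannelImage(pixels=np.clip(blended, 0.0, 1.0), channel=Channel(channel))
    return blended
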