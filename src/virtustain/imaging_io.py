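"""Microscopy image containers and I/O.

Bright-field inputs are multi-plane z-stacks (nominally 7 focal planes,
16-bit grayscale TIFF at 0.1083 um/px); fluorescence targets are single-plane
images of one of three channels (nuclei, lipid droplets, cytoplasm). All
internal computation happens in floating point on the [0, 1] scale; integers
appear only on disk, where values are quantized to 16 bits at write time.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "Channel",
    "BrightfieldStack",
    "ChannelImage",
    "BinaryMask",
    "rescale_dynamic_range",
    "read_stack",
    "read_channel",
    "write_channel",
    "write_stack",
]

NOMINAL_PIXEL_SCALE_UM = 0.1083
MAX_UINT16 = 65535


class Channel(str, enum.Enum):
    NUCLEI = "nuclei"
    LIPIDS = "lipids"
    CYTOPLASM = "cytoplasm"


@dataclass
class BrightfieldStack:
    """Registered multi-plane transmitted-light input, values in [0, 1].

    Planes are ordered by focal depth, bottom to top, exactly as stored in the
    TIFF; no metadata is consulted.
    """

    planes: np.ndarray
    pixel_scale_um: float = NOMINAL_PIXEL_SCALE_UM

    def __post_init__(self):
        self.planes = np.asarray(self.planes)
        if self.planes.ndim != 3 or self.planes.shape[0] < 1:
            raise ValueError("planes must be a (n_planes, H, W) array with n_planes >= 1")
        if self.planes.dtype.kind == "f":
            lo, hi = float(self.planes.min()), float(self.planes.max())
            if lo < -1e-6 or hi > 1 + 1e-6:
                raise ValueError(f"stack values must lie in [0, 1], got [{lo}, {hi}]")

    @property
    def n_planes(self) -> int:
        return self.planes.shape[0]

    @property
    def plane_shape(self) -> tuple[int, int]:
        return self.planes.shape[1:]


@dataclass
class ChannelImage:
    """One fluorescence channel (real or generated), values in [0, 1]."""

    pixels: np.ndarray
    channel: Channel = Channel.NUCLEI

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        self.channel = Channel(self.channel)
        if self.pixels.ndim != 2:
            raise ValueError("ChannelImage requires a 2-D array")
        if self.pixels.dtype.kind == "f":
            lo, hi = float(self.pixels.min()), float(self.pixels.max())
            if lo < -1e-6 or hi > 1 + 1e-6:
                raise ValueError(f"channel values must lie in [0, 1], got [{lo}, {hi}]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class BinaryMask:
    """A {0, 1} mask (e.g. ground-truth nuclear segmentation)."""

    pixels: np.ndarray = field()

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("BinaryMask requires a 2-D array")
        vals = np.unique(self.pixels)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask values must be exactly 0 or 1")
        self.pixels = self.pixels.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def rescale_dynamic_range(image: np.ndarray) -> np.ndarray:
    """Scale an image to [0, 1] using its own dynamic range.

    ``(image - min) / (max - min)`` over the whole image (all planes of a
    stack together). A constant image maps to all zeros. The dynamic range is
    per image, not per dataset, and no percentile clipping is applied.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("cannot rescale an empty image")
    lo = float(image.min())
    hi = float(image.max())
    out = image.astype(np.float64)
    if hi == lo:
        return np.zeros_like(out)
    return (out - lo) / (hi - lo)


def read_stack(path, rescale: bool = False) -> BrightfieldStack:
    """Read a multi-page grayscale TIFF as a bright-field stack.

    Pages become planes in storage order. Raw integer values are kept unless
    ``rescale`` is set, in which case the whole stack is mapped to [0, 1] by
    its joint dynamic range.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    with tifffile.TiffFile(path) as tif:
        pages = [p.asarray() for p in tif.pages]
    shapes = {p.shape for p in pages}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent page shapes in {path}: {sorted(shapes)}")
    if pages[0].ndim != 2:
        raise ValueError(f"{path} is not grayscale (page shape {pages[0].shape})")
    planes = np.stack(pages, axis=0)
    if rescale:
        planes = rescale_dynamic_range(planes)
    return BrightfieldStack(planes=planes)


def read_channel(path, channel: Channel | str = Channel.NUCLEI, rescale: bool = True) -> ChannelImage:
    """Read a single-plane TIFF as a fluorescence channel image."""
    stack = read_stack(path, rescale=False)
    if stack.n_planes != 1:
        raise ValueError(f"expected a single-plane TIFF, got {stack.n_planes} pages")
    pixels = stack.planes[0]
    if rescale:
        pixels = pixels.astype(np.float64) / MAX_UINT16
    return ChannelImage(pixels=pixels, channel=Channel(channel))


def write_channel(image: ChannelImage | np.ndarray, path, bit_depth: int = 16) -> None:
    """Store a [0, 1] image as 16-bit TIFF; value v is stored as round(v*65535)."""
    pixels = image.pixels if isinstance(image, ChannelImage) else np.asarray(image)
    if bit_depth != 16:
        raise ValueError("only 16-bit output is supported")
    if pixels.min() < 0 or pixels.max() > 1:
        raise ValueError("values outside [0, 1] cannot be written losslessly")
    quantized = np.round(pixels * MAX_UINT16).astype(np.uint16)
    tifffile.imwrite(Path(path), quantized, photometric="minisblack")


def write_stack(stack: BrightfieldStack | np.ndarray, path) -> None:
    """Store a [0, 1] stack as a multi-page 16-bit TIFF (plane order preserved)."""
    planes = stack.planes if isinstance(stack, BrightfieldStack) else np.asarray(stack)
    if planes.min() < 0 or planes.max() > 1:
        raise ValueError("values outside [0, 1] cannot be written losslessly")
    quantized = np.round(planes * MAX_UINT16).astype(np.uint16)
    tifffile.imwrite(Path(path), quantized, photometric="minisblack",
                     metadata={"axes": "ZYX"})
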