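"""Neural-network layers on top of the autograd engine.

Mirrors the small subset of a standard deep-learning layer zoo that the
dense U-Net generators and the patch discriminator require. Parameters are
float32; initialisation follows He et al. for convolutions. Every layer is
deterministic given the generator passed at construction time.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .autograd import (
    Tensor,
    batch_norm2d,
    conv2d,
    dropout,
    max_pool2d,
    pixel_shuffle,
)

__all__ = [
    "Module",
    "ModuleList",
    "Sequential",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "LeakyReLU",
    "Sigmoid",
    "Dropout",
    "MaxPool2d",
    "Blur2d",
    "Parameter",
]


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Base class with parameter registration, train/eval mode and state dicts."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray):
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> Iterator[Parameter]:
        for p in self._params.values():
            yield p
        for m in self._modules.values():
            yield from m.parameters()

    def named_state(self, prefix: str = ""):
        for k, p in self._params.items():
            yield prefix + k, p.data
        for k, b in self._buffers.items():
            yield prefix + k, b
        for k, m in self._modules.items():
            yield from m.named_state(prefix + k + ".")

    def state_dict(self) -> dict:
        return {k: v.copy() for k, v in self.named_state()}

    def load_state_dict(self, state: dict):
        own = dict(self.named_state())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing keys in state dict: {sorted(missing)}")
        for k, arr in own.items():
            src = np.asarray(state[k])
            if src.shape != arr.shape:
                raise ValueError(f"shape mismatch for {k}: {src.shape} vs {arr.shape}")
            arr[...] = src

    def train(self, mode: bool = True):
        object.__setattr__(self, "training", mode)
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        self._list = []
        for m in modules:
            self.append(m)

    def append(self, module: Module):
        self._modules[str(len(self._list))] = module
        self._list.append(module)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


class Sequential(Module):
    def __init__(self, *modules):
        super().__init__()
        self.layers = ModuleList(modules)

    def forward(self, x):
        for m in self.layers:
            x = m(x)
        return x


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int | None = None, bias: bool = True):
        super().__init__()
        if padding is None:
            padding = (kernel - 1) // 2
        self.stride, self.padding = stride, padding
        fan_in = in_ch * kernel * kernel
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(0.0, std, size=(out_ch, in_ch, kernel, kernel)))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class BatchNorm2d(Module):
    def __init__(self, n_ch: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.gamma = Parameter(np.ones(n_ch))
        self.beta = Parameter(np.zeros(n_ch))
        self.register_buffer("running_mean", np.zeros(n_ch, dtype=np.float64))
        self.register_buffer("running_var", np.ones(n_ch, dtype=np.float64))

    def forward(self, x):
        return batch_norm2d(
            x, self.gamma, self.beta, self.running_mean, self.running_var,
            training=self.training, momentum=self.momentum, eps=self.eps,
        )


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x):
        return x.leaky_relu(self.slope)


class Sigmoid(Module):
    def forward(self, x):
        return x.sigmoid()


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.rng = rng

    def forward(self, x):
        return dropout(x, self.p, self.rng, self.training)


class MaxPool2d(Module):
    def __init__(self, k: int = 2):
        super().__init__()
        self.k = k

    def forward(self, x):
        return max_pool2d(x, self.k)


class Blur2d(Module):
    """Fixed 2x2 normalized averaging blur (anti-checkerboard after pixel-shuffle).

    Applied depthwise with symmetric handling: pads one row/column (edge mode)
    so the output shape matches the input.
    """

    def forward(self, x):
        n, c, h, w = x.shape
        xr = x.reshape(n * c, 1, h, w)
        # edge-pad one pixel at bottom/right via a concat-free trick: pad with
        # reflect through numpy is not differentiable here, so duplicate edge
        # rows using slicing ops.
        from .autograd import concat

        xr = concat([xr, xr[:, :, h - 1 : h, :]], axis=2)
        xr = concat([xr, xr[:, :, :, w - 1 : w]], axis=3)
        kernel = Tensor(np.full((1, 1, 2, 2), 0.25, dtype=np.float32))
        out = conv2d(xr, kernel, None, stride=1, padding=0)
        return out.reshape(n, c, h, w)


def pixel_shuffle_upsample(x, r: int = 2):
    return pixel_shuffle(x, r)
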