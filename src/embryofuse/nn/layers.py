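"""Neural-network layers on top of the autograd engine.

Layout convention is NCHW for spatial layers and (..., features) for linear
layers.  Every layer takes an ``rng`` (``numpy.random.Generator``) at
construction so whole models are pure functions of their seeds.
"""

from __future__ import annotations

import numpy as np

from embryofuse.nn.autograd import Tensor, concat

__all__ = [
    "Module", "ModuleList", "Sequential", "Parameter",
    "Linear", "Conv2d", "DepthwiseConv2d", "BatchNorm2d", "LayerNorm",
    "ReLU", "GELU", "Sigmoid", "MaxPool2d", "UpsampleNearest2x", "Identity",
    "concat",
]


def Parameter(data) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    training: bool = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()

        def collect(obj):
            if isinstance(obj, Tensor):
                if obj.requires_grad and id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    collect(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    collect(v)

        collect(self)
        return params

    def count_params(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def train(self, mode: bool = True):
        self.training = mode
        for v in vars(self).values():
            for m in (v if isinstance(v, (list, tuple)) else [v]):
                if isinstance(m, Module):
                    m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat name->array map of parameters and buffers, for checkpoints."""
        out: dict[str, np.ndarray] = {}

        def walk(obj, prefix):
            if isinstance(obj, Tensor):
                out[prefix] = obj.data
            elif isinstance(obj, np.ndarray):
                out[prefix] = obj
            elif isinstance(obj, Module):
                for k, v in vars(obj).items():
                    if k != "training":
                        walk(v, f"{prefix}.{k}" if prefix else k)
            elif isinstance(obj, (list, tuple)):
                for i, v in enumerate(obj):
                    walk(v, f"{prefix}.{i}")

        walk(self, "")
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        state = self.state_arrays()
        missing = set(state) ^ set(arrays)
        if missing:
            raise ValueError(f"checkpoint/model state mismatch: {sorted(missing)[:5]}")

        def walk(obj, prefix):
            if isinstance(obj, Tensor):
                obj.data = np.asarray(arrays[prefix], dtype=np.float32)
            elif isinstance(obj, Module):
                for k, v in vars(obj).items():
                    if k == "training":
                        continue
                    name = f"{prefix}.{k}" if prefix else k
                    if isinstance(v, np.ndarray):
                        setattr(obj, k, np.asarray(arrays[name]))
                    else:
                        walk(v, name)
            elif isinstance(obj, (list, tuple)):
                for i, v in enumerate(obj):
                    walk(v, f"{prefix}.{i}")

        walk(self, "")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, modules=()):
        self.items = list(modules)

    def __iter__(self):
        return iter(self.items)

    def __getitem__(self, i):
        return self.items[i]

    def append(self, m):
        self.items.append(m)


class Sequential(Module):
    def __init__(self, *modules):
        self.items = list(modules)

    def forward(self, x):
        for m in self.items:
            x = m(x)
        return x


class Identity(Module):
    def forward(self, x):
        return x


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class GELU(Module):
    def forward(self, x):
        return x.gelu()


class Sigmoid(Module):
    def forward(self, x):
        return x.sigmoid()


class MaxPool2d(Module):
    def forward(self, x):
        return x.maxpool2x2()


class UpsampleNearest2x(Module):
    def forward(self, x):
        return x.upsample_nearest2x()


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True, init_std: float | None = None):
        std = init_std if init_std is not None else np.sqrt(2.0 / in_features)
        self.weight = Parameter(rng.normal(0.0, std, size=(in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x):
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Conv2d(Module):
    """Stride-1 2-D convolution with 'same' padding by default."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, padding: int | None = None,
                 bias: bool = True):
        k = kernel_size
        self.padding = (k - 1) // 2 if padding is None else padding
        fan_in = in_channels * k * k
        self.weight = Parameter(
            rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_channels, in_channels, k, k))
        )
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x):
        return x.conv2d(self.weight, self.bias, padding=self.padding)


class DepthwiseConv2d(Module):
    def __init__(self, channels: int, kernel_size: int, rng: np.random.Generator,
                 padding: int | None = None, bias: bool = True):
        k = kernel_size
        self.padding = (k - 1) // 2 if padding is None else padding
        self.weight = Parameter(
            rng.normal(0.0, np.sqrt(2.0 / (k * k)), size=(channels, k, k))
        )
        self.bias = Parameter(np.zeros(channels)) if bias else None

    def forward(self, x):
        return x.depthwise_conv2d(self.weight, self.bias, padding=self.padding)


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.eps = eps
        self.momentum = momentum

    def forward(self, x):
        if self.training:
            mean = x.mean(axis=(0, 2, 3), keepdims=True)
            centered = x - mean
            var = (centered * centered).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean += self.momentum * (
                mean.data.reshape(-1) - self.running_mean)
            self.running_var += self.momentum * (
                var.data.reshape(-1) - self.running_var)
            xhat = centered * ((var + self.eps) ** -0.5)
        else:
            mean = self.running_mean.reshape(1, -1, 1, 1)
            var = self.running_var.reshape(1, -1, 1, 1)
            xhat = (x - mean) * ((var + self.eps) ** -0.5)
        return xhat * self.gamma.reshape(1, -1, 1, 1) + self.beta.reshape(1, -1, 1, 1)


class LayerNorm(Module):
    """Normalization over the trailing ``features`` axis."""

    def __init__(self, features: int, eps: float = 1e-6):
        self.gamma = Parameter(np.ones(features))
        self.beta = Parameter(np.zeros(features))
        self.eps = eps

    def forward(self, x):
        mean = x.mean(axis=-1, keepdims=True)
        centered = x - mean
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered * ((var + self.eps) ** -0.5) * self.gamma + self.beta
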