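"""Layer modules with parameter registration, train/eval modes and
state-dict (de)serialisation, in the style familiar from deep-learning
frameworks but backed by the NumPy autodiff engine."""

from __future__ import annotations

from collections import OrderedDict

import numpy as np

from . import functional as F
from .tensor import Tensor

_DEFAULT_DTYPE = np.float32
_RNG = np.random.default_rng(0)


def manual_seed(seed: int) -> None:
    """Seed the global generator used for parameter initialisation."""
    global _RNG
    _RNG = np.random.default_rng(seed)


def _rng() -> np.random.Generator:
    return _RNG


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=_DEFAULT_DTYPE), requires_grad=True)


class Module:
    """Base class: child modules, parameters and buffers are registered via
    attribute assignment, like the convention established by torch.nn."""

    def __init__(self):
        object.__setattr__(self, "_parameters", OrderedDict())
        object.__setattr__(self, "_modules", OrderedDict())
        object.__setattr__(self, "_buffers", OrderedDict())
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._parameters[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    # -- traversal ---------------------------------------------------------
    def named_parameters(self, prefix: str = ""):
        for name, p in self._parameters.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = ""):
        for name, b in self._buffers.items():
            yield prefix + name, b
        for name, m in self._modules.items():
            yield from m.named_buffers(prefix + name + ".")

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def num_parameters(self) -> int:
        return int(np.sum([p.data.size for p in self.parameters()]))

    # -- modes / grads -----------------------------------------------------
    def train(self, mode: bool = True):
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # -- state -------------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        missing = (set(params) | set(buffers)) - set(state)
        if missing:
            raise KeyError(f"state dict missing entries: {sorted(missing)[:5]} ...")
        for name, p in params.items():
            arr = np.asarray(state[name], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for {name}: checkpoint {arr.shape}, "
                    f"model {p.data.shape}")
            p.data = arr.copy()
        for name, b in buffers.items():
            b[...] = state[name]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    """3x3/1x1/... convolution with Kaiming-normal weight initialisation
    (fan-in, gain sqrt(2) for the rectifier nonlinearity)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 padding: int = 0, dilation: int = 1, bias: bool = True):
        super().__init__()
        self.stride, self.padding, self.dilation = stride, padding, dilation
        fan_in = in_ch * kernel * kernel
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(_rng().normal(0.0, std, (out_ch, in_ch, kernel, kernel)))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x):
        return F.conv2d(x, self.weight, self.bias, stride=self.stride,
                        padding=self.padding, dilation=self.dilation)


class Deconv2x2(Module):
    """Transposed convolution, kernel 2 stride 2 — learned exact x2 upsampling."""

    def __init__(self, in_ch: int, out_ch: int, bias: bool = True):
        super().__init__()
        std = np.sqrt(2.0 / (in_ch * 4))
        self.weight = Parameter(_rng().normal(0.0, std, (in_ch, out_ch, 2, 2)))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x):
        return F.deconv2x2(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.weight = Parameter(np.ones(channels))
        self.bias = Parameter(np.zeros(channels))
        self.register_buffer("running_mean", np.zeros(channels, dtype=_DEFAULT_DTYPE))
        self.register_buffer("running_var", np.ones(channels, dtype=_DEFAULT_DTYPE))

    def forward(self, x):
        return F.batch_norm2d(x, self.weight, self.bias, self.running_mean,
                              self.running_var, training=self.training,
                              momentum=self.momentum, eps=self.eps)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True):
        super().__init__()
        std = np.sqrt(2.0 / in_features)
        self.weight = Parameter(_rng().normal(0.0, std, (out_features, in_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x):
        return F.linear(x, self.weight, self.bias)


class ReLU(Module):
    def forward(self, x):
        return F.relu(x)


class Sigmoid(Module):
    def forward(self, x):
        return F.sigmoid(x)


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            setattr(self, f"layer{i}", layer)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class ConvBNReLU(Sequential):
    def __init__(self, in_ch, out_ch, kernel, stride=1, padding=0, dilation=1):
        super().__init__(
            Conv2d(in_ch, out_ch, kernel, stride=stride, padding=padding,
                   dilation=dilation, bias=False),
            BatchNorm2d(out_ch),
            ReLU(),
        )
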