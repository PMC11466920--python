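"""Layer/module system: parameter registration, train/eval mode, state dicts."""

from __future__ import annotations

from collections import OrderedDict

import numpy as np

from . import init
from .functional import conv2d, conv_transpose2d, gelu, relu
from .tensor import Tensor

__all__ = [
    "Parameter",
    "Module",
    "ModuleList",
    "Linear",
    "Conv2d",
    "ConvTranspose2d",
    "LayerNorm",
    "BatchNorm2d",
    "Mlp",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", OrderedDict())
        object.__setattr__(self, "_buffers", OrderedDict())
        object.__setattr__(self, "_children", OrderedDict())
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._children[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = np.asarray(value, dtype=np.float64)
        object.__setattr__(self, name, self._buffers[name])

    def _set_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = np.asarray(value, dtype=np.float64)
        object.__setattr__(self, name, self._buffers[name])

    # -------------------------------------------------------------- traversal
    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for name, child in self._children.items():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = ""):
        for name, b in self._buffers.items():
            yield prefix + name, b
        for name, child in self._children.items():
            yield from child.named_buffers(prefix + name + ".")

    def modules(self):
        yield self
        for child in self._children.values():
            yield from child.modules()

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    # ------------------------------------------------------------------ modes
    def train(self):
        for m in self.modules():
            object.__setattr__(m, "training", True)
        return self

    def eval(self):
        for m in self.modules():
            object.__setattr__(m, "training", False)
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    # ------------------------------------------------------------- state dict
    def state_dict(self) -> "OrderedDict[str, np.ndarray]":
        state = OrderedDict()
        for name, p in self.named_parameters():
            state[name] = p.data.copy()
        for name, b in self.named_buffers():
            state["buffer." + name] = b.copy()
        return state

    def load_state_dict(self, state) -> None:
        params = dict(self.named_parameters())
        expected = set(params) | {"buffer." + n for n, _ in self.named_buffers()}
        missing = expected - set(state)
        if missing:
            raise KeyError(f"state dict missing entries: {sorted(missing)[:5]} ...")
        for name, value in state.items():
            if name.startswith("buffer."):
                self._assign_buffer(name[len("buffer.") :], value)
            else:
                if params[name].shape != np.shape(value):
                    raise ValueError(f"shape mismatch for {name}")
                params[name].data = np.asarray(value, dtype=np.float64).copy()

    def _assign_buffer(self, dotted: str, value) -> None:
        obj = self
        parts = dotted.split(".")
        for part in parts[:-1]:
            obj = obj._children[part]
        obj._set_buffer(parts[-1], np.asarray(value, dtype=np.float64).copy())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._items: list[Module] = []
        for m in mods:
            self.append(m)

    def append(self, mod: Module):
        setattr(self, str(len(self._items)), mod)
        self._items.append(mod)
        return self

    def __iter__(self):
        return iter(self._items)

    def __len__(self):
        return len(self._items)

    def __getitem__(self, idx):
        return self._items[idx]


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Parameter(init.trunc_normal((out_features, in_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        from .functional import matmul

        y = matmul(x, self.weight.swapaxes(0, 1))
        if self.bias is not None:
            y = y + self.bias
        return y


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1, padding: int = 0, bias: bool = True):
        super().__init__()
        self.stride = stride
        self.padding = padding
        fan_in = in_ch * kernel * kernel
        self.weight = Parameter(init.kaiming_normal((out_ch, in_ch, kernel, kernel), fan_in))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class ConvTranspose2d(Module):
    """Upsampling deconvolution with kernel == stride (exact extent doubling for k=2)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 2, stride: int = 2, bias: bool = True):
        super().__init__()
        if kernel != stride:
            raise ValueError("kernel must equal stride")
        self.stride = stride
        fan_in = in_ch
        self.weight = Parameter(init.kaiming_normal((in_ch, out_ch, kernel, kernel), fan_in))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv_transpose2d(x, self.weight, self.bias, stride=self.stride)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-6):
        super().__init__()
        self.eps = eps
        self.weight = Parameter(np.ones(dim))
        self.bias = Parameter(np.zeros(dim))

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centred = x - mu
        var = (centred * centred).mean(axis=-1, keepdims=True)
        xhat = centred / (var + self.eps) ** 0.5
        return xhat * self.weight + self.bias


class BatchNorm2d(Module):
    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(num_features))
        self.bias = Parameter(np.zeros(num_features))
        self.register_buffer("running_mean", np.zeros(num_features))
        self.register_buffer("running_var", np.ones(num_features))

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            centred = x - mu
            var = (centred * centred).mean(axis=(0, 2, 3), keepdims=True)
            # update running statistics with the (biased) batch moments
            m = self.momentum
            self._set_buffer(
                "running_mean", (1 - m) * self.running_mean + m * mu.data.reshape(-1)
            )
            self._set_buffer(
                "running_var", (1 - m) * self.running_var + m * var.data.reshape(-1)
            )
            xhat = centred / (var + self.eps) ** 0.5
        else:
            mu = Tensor(self.running_mean.reshape(1, -1, 1, 1))
            var = Tensor(self.running_var.reshape(1, -1, 1, 1))
            xhat = (x - mu) / (var + self.eps) ** 0.5
        w = self.weight.reshape(1, -1, 1, 1)
        b = self.bias.reshape(1, -1, 1, 1)
        return xhat * w + b


class Mlp(Module):
    """Two-layer feed-forward block with GELU, as used inside transformer blocks."""

    def __init__(self, dim: int, hidden: int):
        super().__init__()
        self.fc1 = Linear(dim, hidden)
        self.fc2 = Linear(hidden, dim)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(gelu(self.fc1(x)))
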