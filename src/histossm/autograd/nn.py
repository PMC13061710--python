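"""Layer abstractions over the autograd tensor."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor
from .ops import depthwise_conv2d

__all__ = ["Module", "Linear", "DepthwiseConv2d", "LayerNorm", "Dropout"]


class Module:
    """Base class; collects parameters from attributes in insertion order."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
        params, seen = [], set()

        def collect(obj):
            if isinstance(obj, Tensor):
                if obj.requires_grad and id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in obj.__dict__.values():
                    collect(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    collect(v)

        collect(self)
        return params

    def modules(self) -> list["Module"]:
        mods = [self]

        def collect(obj):
            if isinstance(obj, Module):
                mods.append(obj)
                for v in obj.__dict__.values():
                    collect(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    collect(v)

        for v in self.__dict__.values():
            collect(v)
        return mods

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {str(i): p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("state dict size mismatch")
        for i, p in enumerate(params):
            p.data = np.asarray(state[str(i)], dtype=p.data.dtype).reshape(p.data.shape)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    """Affine map over the last axis."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 bias: bool = True, dtype=np.float32):
        super().__init__()
        scale = np.sqrt(2.0 / (in_dim + out_dim))
        self.weight = Tensor(
            rng.normal(0.0, scale, size=(in_dim, out_dim)).astype(dtype),
            requires_grad=True,
        )
        self.bias = (
            Tensor(np.zeros(out_dim, dtype=dtype), requires_grad=True) if bias else None
        )

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class DepthwiseConv2d(Module):
    def __init__(self, channels: int, k: int, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        scale = np.sqrt(1.0 / (k * k))
        self.weight = Tensor(
            rng.normal(0.0, scale, size=(k, k, channels)).astype(dtype),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(channels, dtype=dtype), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return depthwise_conv2d(x, self.weight, self.bias)


class LayerNorm(Module):
    """Normalization over the last (channel) axis."""

    def __init__(self, dim: int, eps: float = 1e-5, dtype=np.float32):
        super().__init__()
        self.eps = eps
        self.gamma = Tensor(np.ones(dim, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(dim, dtype=dtype), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xn = xc / ((var + self.eps).sqrt())
        return xn * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout p must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = 1.0 - self.p
        mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * Tensor(mask)
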