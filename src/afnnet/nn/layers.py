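"""Neural-network modules built on the autograd engine.

Parameter registration mirrors the familiar module/state-dict pattern:
submodules and parameters assigned as attributes are discovered by name,
checkpoints are flat dicts keyed by dotted paths.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, conv2d, matmul, softmax

__all__ = [
    "Parameter",
    "Module",
    "Conv2d",
    "BatchNorm2d",
    "LayerNorm",
    "Linear",
    "MultiHeadSelfAttention",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


class Module:
    def __init__(self):
        self.training = True

    # -- introspection -----------------------------------------------------

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield prefix + name, value
            elif isinstance(value, Module):
                yield from value.named_parameters(prefix + name + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{prefix}{name}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def modules(self):
        yield self
        for value in vars(self).values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_buffers(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, np.ndarray):
                yield prefix + name, value
            elif isinstance(value, Module):
                yield from value.named_buffers(prefix + name + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{prefix}{name}.{i}.")

    # -- mode / state ------------------------------------------------------

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({"buffer." + n: b.copy() for n, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict):
        for name, p in self.named_parameters():
            arr = np.asarray(state[name])
            if arr.shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for parameter {name!r}: "
                    f"checkpoint {arr.shape} vs model {p.data.shape}"
                )
            p.data = arr.astype(p.data.dtype)
        buffers = dict(self.named_buffers())
        for key, arr in state.items():
            if key.startswith("buffer."):
                name = key[len("buffer."):]
                buffers[name][...] = np.asarray(arr)

    def astype(self, dtype):
        """Cast all parameters and float buffers in place (e.g. for float64 grad checks)."""
        for p in self.parameters():
            p.data = p.data.astype(dtype)
        for _, b in self.named_buffers():
            if b.dtype.kind == "f":
                b[...] = b.astype(dtype)
        return self

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


# ---------------------------------------------------------------------------


def kaiming_uniform(rng: np.random.Generator, shape, fan_in: int, dtype=np.float32):
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(dtype)


def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02, dtype=np.float32):
    vals = rng.normal(0.0, std, size=shape)
    vals = np.clip(vals, -2 * std, 2 * std)
    return vals.astype(dtype)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 padding: int = 0, groups: int = 1, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.stride, self.padding, self.groups = stride, padding, groups
        fan_in = (in_ch // groups) * kernel * kernel
        self.weight = Parameter(
            kaiming_uniform(rng, (out_ch, in_ch // groups, kernel, kernel), fan_in)
        )
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding, self.groups)


class BatchNorm2d(Module):
    def __init__(self, num_ch: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Parameter(np.ones(num_ch, dtype=np.float32))
        self.beta = Parameter(np.zeros(num_ch, dtype=np.float32))
        self.running_mean = np.zeros(num_ch, dtype=np.float32)
        self.running_var = np.ones(num_ch, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        C = x.shape[1]
        shape = (1, C, 1, 1)
        if self.training:
            m = x.mean(axis=(0, 2, 3), keepdims=True)
            v = ((x - m) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            n = x.data.size / C
            self.running_mean += self.momentum * (m.data.reshape(C) - self.running_mean)
            unbiased = v.data.reshape(C) * (n / max(n - 1, 1))
            self.running_var += self.momentum * (unbiased - self.running_var)
        else:
            m = Tensor(self.running_mean.reshape(shape).astype(x.dtype))
            v = Tensor(self.running_var.reshape(shape).astype(x.dtype))
        xhat = (x - m) / ((v + self.eps) ** 0.5)
        return xhat * self.gamma.reshape(shape) + self.beta.reshape(shape)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-6):
        super().__init__()
        self.eps = eps
        self.gamma = Parameter(np.ones(dim, dtype=np.float32))
        self.beta = Parameter(np.zeros(dim, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        m = x.mean(axis=-1, keepdims=True)
        v = ((x - m) ** 2).mean(axis=-1, keepdims=True)
        return (x - m) / ((v + self.eps) ** 0.5) * self.gamma + self.beta


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, bias: bool = True,
                 rng: np.random.Generator | None = None, init: str = "trunc_normal"):
        super().__init__()
        rng = rng or np.random.default_rng()
        if init == "trunc_normal":
            w = trunc_normal(rng, (in_dim, out_dim))
        else:
            w = kaiming_uniform(rng, (in_dim, out_dim), in_dim)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_dim, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = matmul(x, self.weight)
        if self.bias is not None:
            out = out + self.bias
        return out


class MultiHeadSelfAttention(Module):
    """Standard scaled-dot-product self-attention over a (N, T, d) token array."""

    def __init__(self, dim: int, heads: int, rng: np.random.Generator | None = None):
        super().__init__()
        if dim % heads:
            raise ValueError(f"embedding dim {dim} not divisible by heads {heads}")
        self.heads = heads
        self.head_dim = dim // heads
        self.qkv = Linear(dim, 3 * dim, rng=rng)
        self.proj = Linear(dim, dim, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        N, T, d = x.shape
        h, hd = self.heads, self.head_dim
        qkv = self.qkv(x).reshape(N, T, 3, h, hd).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]
        attn = softmax(matmul(q, k.transpose(0, 1, 3, 2)) * (hd ** -0.5), axis=-1)
        out = matmul(attn, v).transpose(0, 2, 1, 3).reshape(N, T, d)
        return self.proj(out)
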