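"""Neural-network building blocks on top of the autodiff tensor.

Layers hold their parameters as :class:`Tensor` objects with
``requires_grad=True``; a module exposes ``parameters()`` for the optimizer
and ``state_dict``/``load_state_dict`` for checkpointing.  Initialization is
Glorot-uniform from an explicit ``numpy.random.Generator`` so every model is
seed-deterministic.
"""

from __future__ import annotations

import numpy as np

from .tensor import DTYPE, Tensor, conv1d, gather_rows


def glorot(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> Tensor:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape).astype(DTYPE),
                  requires_grad=True)


class Module:
    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def state_dict(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for name, v in self.__dict__.items():
            if isinstance(v, Tensor) and v.requires_grad:
                out[name] = v.data.copy()
            elif isinstance(v, Module):
                for k, arr in v.state_dict().items():
                    out[f"{name}.{k}"] = arr
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        for k, arr in item.state_dict().items():
                            out[f"{name}.{i}.{k}"] = arr
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = self._named_parameters()
        missing = set(own) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)}")
        for k, t in own.items():
            if t.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            t.data = state[k].astype(DTYPE, copy=True)

    def _named_parameters(self) -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for name, v in self.__dict__.items():
            if isinstance(v, Tensor) and v.requires_grad:
                out[name] = v
            elif isinstance(v, Module):
                for k, t in v._named_parameters().items():
                    out[f"{name}.{k}"] = t
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        for k, t in item._named_parameters().items():
                            out[f"{name}.{i}.{k}"] = t
        return out


class Dense(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.w = glorot(rng, (d_in, d_out), d_in, d_out)
        self.b = Tensor(np.zeros(d_out, dtype=DTYPE), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Conv1d(Module):
    """Same-padded convolution over (B, L, C) sequences."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1):
        self.w = glorot(rng, (kernel, c_in, c_out), kernel * c_in, c_out)
        self.b = Tensor(np.zeros(c_out, dtype=DTYPE), requires_grad=True)
        self.stride = stride

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d(x, self.w, self.b, stride=self.stride)


class SelfAttention(Module):
    """Single-head scaled dot-product self-attention with key padding mask."""

    def __init__(self, d: int, rng: np.random.Generator):
        self.wq = Dense(d, d, rng)
        self.wk = Dense(d, d, rng)
        self.wv = Dense(d, d, rng)
        self.scale = 1.0 / np.sqrt(d)

    def __call__(self, x: Tensor, mask: np.ndarray | None = None) -> Tensor:
        q, k, v = self.wq(x), self.wk(x), self.wv(x)
        scores = (q @ k.swapaxes(-1, -2)) * self.scale  # (B, L, L)
        if mask is not None:
            neg = (1.0 - mask[:, None, :]) * np.float32(-1e9)
            scores = scores + Tensor(neg)
        return scores.softmax(axis=-1) @ v


class MultiHeadAttention(Module):
    def __init__(self, d: int, heads: int, rng: np.random.Generator):
        if d % heads:
            raise ValueError("embed dim must divide head count")
        self.heads = heads
        self.dk = d // heads
        self.wq = Dense(d, d, rng)
        self.wk = Dense(d, d, rng)
        self.wv = Dense(d, d, rng)
        self.wo = Dense(d, d, rng)

    def __call__(self, x: Tensor, mask: np.ndarray | None = None) -> Tensor:
        B, L, d = x.shape
        h, dk = self.heads, self.dk

        def split(t: Tensor) -> Tensor:  # (B, L, d) -> (B, h, L, dk)
            return t.reshape(B, L, h, dk).transpose(0, 2, 1, 3)

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(dk))  # (B,h,L,L)
        if mask is not None:
            neg = (1.0 - mask[:, None, None, :]) * np.float32(-1e9)
            scores = scores + Tensor(neg)
        ctx = scores.softmax(axis=-1) @ v  # (B,h,L,dk)
        ctx = ctx.transpose(0, 2, 1, 3).reshape(B, L, d)
        return self.wo(ctx)


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(d, dtype=DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros(d, dtype=DTYPE), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered / (var + self.eps).sqrt() * self.gamma + self.beta


class Embedding(Module):
    def __init__(self, vocab: int, d: int, rng: np.random.Generator):
        self.table = Tensor(
            rng.normal(0.0, 0.02, size=(vocab, d)).astype(DTYPE), requires_grad=True)

    def __call__(self, tokens: np.ndarray) -> Tensor:
        return gather_rows(self.table, tokens)


class TransformerBlock(Module):
    """Pre-norm encoder block: attention and feed-forward with residuals."""

    def __init__(self, d: int, heads: int, d_ff: int, rng: np.random.Generator):
        self.attn = MultiHeadAttention(d, heads, rng)
        self.norm1 = LayerNorm(d)
        self.ff1 = Dense(d, d_ff, rng)
        self.ff2 = Dense(d_ff, d, rng)
        self.norm2 = LayerNorm(d)

    def __call__(self, x: Tensor, mask: np.ndarray | None = None) -> Tensor:
        x = x + self.attn(self.norm1(x), mask)
        return x + self.ff2(self.ff1(self.norm2(x)).relu())


def sinusoidal_positions(length: int, d: int) -> np.ndarray:
    pos = np.arange(length)[:, None].astype(np.float64)
    i = np.arange(d)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / d)
    enc = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return enc.astype(DTYPE)


class Adam:
    """Standard Adam with bias correction."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            update = mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay:
                update = update + self.weight_decay * p.data  # decoupled decay
            p.data -= (self.lr * update).astype(DTYPE)
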