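"""Layers and an AdamW optimizer built on the autograd core."""

from __future__ import annotations

import numpy as np

from .autograd import Parameter, Tensor, as_tensor

__all__ = ["Module", "Linear", "LayerNorm", "Dropout", "AdamW", "cross_entropy"]


class Module:
    """Base class: recursive parameter collection and train/eval switching."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()
        for value in vars(self).values():
            for p in _collect(value):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def modules(self) -> list["Module"]:
        mods: list[Module] = [self]
        for value in vars(self).values():
            mods.extend(_collect_modules(value))
        return mods

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: list[np.ndarray]):
        params = self.parameters()
        if len(params) != len(state):
            raise ValueError("state size mismatch")
        for p, s in zip(params, state):
            p.data = s.copy()

    def zero_init(self):
        """Zero every parameter (used by residual-identity tests)."""
        for p in self.parameters():
            p.data[...] = 0.0
        return self


def _collect(value):
    if isinstance(value, Parameter):
        yield value
    elif isinstance(value, Module):
        yield from value.parameters()
    elif isinstance(value, (list, tuple)):
        for v in value:
            yield from _collect(v)
    elif isinstance(value, dict):
        for v in value.values():
            yield from _collect(v)


def _collect_modules(value):
    if isinstance(value, Module):
        yield from value.modules()
    elif isinstance(value, (list, tuple)):
        for v in value:
            yield from _collect_modules(v)
    elif isinstance(value, dict):
        for v in value.values():
            yield from _collect_modules(v)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 bias: bool = True):
        scale = np.sqrt(2.0 / in_dim)
        self.weight = Parameter(rng.normal(0.0, scale, size=(in_dim, out_dim)))
        self.bias = Parameter(np.zeros(out_dim)) if bias else None
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        out = as_tensor(x) @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class LayerNorm(Module):
    """Per-vector normalization over the last axis (epsilon 1e-12)."""

    def __init__(self, dim: int, eps: float = 1e-12):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered ** 2).mean(axis=-1, keepdims=True)
        normed = centered * ((var + self.eps) ** -0.5)
        return normed * self.gamma + self.beta

    def normalized(self, x: Tensor) -> Tensor:
        """Normalization without the affine part (mean 0, variance 1)."""
        x = as_tensor(x)
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered ** 2).mean(axis=-1, keepdims=True)
        return centered * ((var + self.eps) ** -0.5)


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator | None = None):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng if rng is not None else np.random.default_rng(0)
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return as_tensor(x)
        keep = (self.rng.random(as_tensor(x).shape) >= self.p) / (1.0 - self.p)
        return as_tensor(x) * keep


class AdamW(Module):
    """Decoupled-weight-decay Adam (beta1=0.9, beta2=0.999 defaults)."""

    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                 + self.weight_decay * p.data)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean categorical cross-entropy for integer labels over the last axis."""
    logp = as_tensor(logits).log_softmax(axis=-1)
    labels = np.asarray(labels)
    onehot = np.zeros(logp.shape)
    onehot[np.arange(labels.size), labels] = 1.0
    return -(logp * onehot).sum() * (1.0 / labels.size)
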