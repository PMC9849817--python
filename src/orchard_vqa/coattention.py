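"""Self-attention (SA) and guided co-attention (CA) units, the modular
co-attention layer SA(Y)-SCA(X,Y), depth-L stacking, and attended reduction
to single vectors.

All units are pre-layer-norm residual blocks: with zero-initialized sublayer
weights each unit (and the whole stack) is the identity.  X is the image
sequence, Y the question sequence; in the CA unit queries come from X and
keys/values from Y (question-guided image attention); a config flag can swap
the roles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, as_tensor
from .errors import InvalidConfigError, InvalidInputError
from .nn import Dropout, LayerNorm, Linear, Module

__all__ = ["AttnConfig", "MultiHeadAttention", "SAUnit", "CAUnit",
           "MCAStack", "AttendedReduce", "multi_head_attention"]

_NEG = -1e9


@dataclass
class AttnConfig:
    heads: int = 8
    hidden: int = 512
    ffn_mult: int = 4
    L: int = 4
    dropout: float = 0.5
    eps: float = 1e-12
    swap_ca_roles: bool = False   # queries from the question instead of the image

    def validate(self) -> "AttnConfig":
        if self.hidden % self.heads:
            raise InvalidConfigError(
                f"hidden ({self.hidden}) must be divisible by heads ({self.heads})")
        if self.L < 1:
            raise InvalidConfigError("MCA depth L must be >= 1")
        return self


class MultiHeadAttention(Module):
    """Scaled dot-product attention: per-head softmax over unmasked keys,
    head concatenation, output projection.  Queries whose keys are all masked
    produce exactly zero output."""

    def __init__(self, cfg: AttnConfig, rng: np.random.Generator):
        cfg.validate()
        h = cfg.hidden
        self.cfg = cfg
        self.wq = Linear(h, h, rng)
        self.wk = Linear(h, h, rng)
        self.wv = Linear(h, h, rng)
        self.wo = Linear(h, h, rng)
        self.last_weights: np.ndarray | None = None
        self.training = True

    def _split(self, x: Tensor) -> Tensor:
        b, t, h = x.shape
        nh = self.cfg.heads
        return x.reshape(b, t, nh, h // nh).transpose(0, 2, 1, 3)

    def __call__(self, q_in, k_in, v_in,
                 key_mask: np.ndarray | None = None) -> Tensor:
        q = self._split(self.wq(as_tensor(q_in)))      # (B, nh, Tq, dh)
        k = self._split(self.wk(as_tensor(k_in)))
        v = self._split(self.wv(as_tensor(v_in)))
        dh = q.shape[-1]
        scores = q @ k.transpose(0, 1, 3, 2) * (1.0 / np.sqrt(dh))
        if key_mask is not None:
            m = np.asarray(key_mask, dtype=bool)       # (B, Tk)
            scores = scores + np.where(m, 0.0, _NEG)[:, None, None, :]
        weights = scores.softmax(axis=-1)
        if key_mask is not None:
            m = np.asarray(key_mask, dtype=bool)
            # exact zeros on masked keys; zero rows when every key is masked
            weights = weights * m[:, None, None, :].astype(float)
        self.last_weights = weights.data
        out = weights @ v                              # (B, nh, Tq, dh)
        b, nh, tq, _ = out.shape
        out = out.transpose(0, 2, 1, 3).reshape(b, tq, nh * dh)
        return self.wo(out)


def multi_head_attention(q_in, k_in, v_in, cfg: AttnConfig,
                         key_mask: np.ndarray | None = None,
                         rng: np.random.Generator | None = None) -> Tensor:
    """Functional wrapper around a freshly initialized MultiHeadAttention."""
    mha = MultiHeadAttention(cfg, rng if rng is not None else np.random.default_rng(0))
    return mha(q_in, k_in, v_in, key_mask)


class _FeedForward(Module):
    def __init__(self, cfg: AttnConfig, rng: np.random.Generator):
        h = cfg.hidden
        self.fc1 = Linear(h, h * cfg.ffn_mult, rng)
        self.fc2 = Linear(h * cfg.ffn_mult, h, rng)
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())


class SAUnit(Module):
    """Pre-norm multi-head self-attention + residual, then pre-norm
    feed-forward + residual."""

    def __init__(self, cfg: AttnConfig, rng: np.random.Generator,
                 drop_rng: np.random.Generator | None = None):
        self.mha = MultiHeadAttention(cfg, rng)
        self.ffn = _FeedForward(cfg, rng)
        self.ln1 = LayerNorm(cfg.hidden, eps=cfg.eps)
        self.ln2 = LayerNorm(cfg.hidden, eps=cfg.eps)
        self.drop = Dropout(cfg.dropout, drop_rng)
        self.training = True

    def __call__(self, s, mask: np.ndarray | None = None) -> Tensor:
        s = as_tensor(s)
        n = self.ln1(s)
        s = s + self.drop(self.mha(n, n, n, key_mask=mask))
        s = s + self.drop(self.ffn(self.ln2(s)))
        return s


class CAUnit(Module):
    """Guided attention: queries from X (residual path), keys/values from Y."""

    def __init__(self, cfg: AttnConfig, rng: np.random.Generator,
                 drop_rng: np.random.Generator | None = None):
        self.mha = MultiHeadAttention(cfg, rng)
        self.ffn = _FeedForward(cfg, rng)
        self.ln_x = LayerNorm(cfg.hidden, eps=cfg.eps)
        self.ln_y = LayerNorm(cfg.hidden, eps=cfg.eps)
        self.ln2 = LayerNorm(cfg.hidden, eps=cfg.eps)
        self.drop = Dropout(cfg.dropout, drop_rng)
        self.training = True

    def __call__(self, x, y, y_mask: np.ndarray | None = None) -> Tensor:
        x = as_tensor(x)
        ny = self.ln_y(as_tensor(y))
        x = x + self.drop(self.mha(self.ln_x(x), ny, ny, key_mask=y_mask))
        x = x + self.drop(self.ffn(self.ln2(x)))
        return x


class MCAStack(Module):
    """L layers of SA(Y)-SCA(X,Y): per layer Y <- SA(Y); X <- SA(X);
    X <- CA(X, Y).  Returns both final sequences."""

    def __init__(self, cfg: AttnConfig, rng: np.random.Generator,
                 drop_rng: np.random.Generator | None = None):
        cfg.validate()
        self.cfg = cfg
        self.sa_y = [SAUnit(cfg, rng, drop_rng) for _ in range(cfg.L)]
        self.sa_x = [SAUnit(cfg, rng, drop_rng) for _ in range(cfg.L)]
        self.ca = [CAUnit(cfg, rng, drop_rng) for _ in range(cfg.L)]
        self.training = True

    def __call__(self, x, y, x_mask: np.ndarray | None = None,
                 y_mask: np.ndarray | None = None) -> tuple[Tensor, Tensor]:
        x, y = as_tensor(x), as_tensor(y)
        for sa_y, sa_x, ca in zip(self.sa_y, self.sa_x, self.ca):
            y = sa_y(y, mask=y_mask)
            x = sa_x(x, mask=x_mask)
            if self.cfg.swap_ca_roles:
                y = ca(y, x, y_mask=x_mask)
            else:
                x = ca(x, y, y_mask=y_mask)
        return x, y

    def attention_maps(self) -> list[np.ndarray]:
        """Per-layer CA attention weights from the last forward pass."""
        return [ca.mha.last_weights for ca in self.ca
                if ca.mha.last_weights is not None]


class AttendedReduce(Module):
    """Learned single-glimpse reduction: linear score, softmax over unmasked
    positions, weighted sum."""

    def __init__(self, hidden: int, rng: np.random.Generator):
        self.score = Linear(hidden, 1, rng)
        self.last_weights: np.ndarray | None = None
        self.training = True

    def __call__(self, s, mask: np.ndarray | None = None) -> Tensor:
        s = as_tensor(s)
        b, t, _ = s.shape
        if mask is not None:
            mask = np.asarray(mask, dtype=bool)
            if not mask.any(axis=-1).all():
                raise InvalidInputError("attended_reduce on a fully masked sequence")
        scores = self.score(s).reshape(b, t)
        if mask is not None:
            scores = scores + np.where(mask, 0.0, _NEG)
        weights = scores.softmax(axis=-1)
        if mask is not None:
            weights = weights * mask.astype(float)
        self.last_weights = weights.data
        return (weights.reshape(b, 1, t) @ s).reshape(b, s.shape[-1])
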