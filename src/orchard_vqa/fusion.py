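"""Tucker-decomposed bilinear fusion with the element-wise-squared image
projection, the low-rank core constraint, baseline fusions, a materialized
full-tensor oracle, and the additive-projection classifier head.

The bilinear answer score is ``f = ((T_c x1 (q W_q)) x2 (v W_v)) x3 W_o + b``:
both inputs are projected into a small core space, contracted with the core
tensor over the question then image axes, expanded to answer logits, and
biased.  The squared variant squares the projected image vector element-wise
before contraction, emphasizing image features.  The full d_q x d_v x |A|
tensor is never materialized outside the test-only oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Parameter, Tensor, as_tensor, concat
from .errors import InvalidInputError
from .nn import LayerNorm, Linear, Module

__all__ = [
    "FusionOutput", "LowRankCore", "TuckerFusion", "ClassifierHead",
    "BaselineFusion", "tucker_fuse", "squared_tucker_fuse",
    "build_lowrank_core", "full_bilinear_oracle", "baseline_fuse",
]

_ORACLE_GUARD = 2_000_000  # max entries of the materialized tensor


@dataclass
class FusionOutput:
    logits: np.ndarray
    probabilities: np.ndarray
    prediction: int

    @classmethod
    def from_logits(cls, logits: np.ndarray) -> "FusionOutput":
        logits = np.asarray(logits, dtype=np.float64)
        shifted = logits - logits.max()
        p = np.exp(shifted)
        p /= p.sum()
        return cls(logits=logits, probabilities=p, prediction=int(np.argmax(logits)))


class LowRankCore(Module):
    """Core tensor whose t_o slices are sums of R rank-one factor pairs.

    Parameter count is t_o * R * (t_q + t_v).
    """

    def __init__(self, t_q: int, t_v: int, t_o: int, R: int,
                 rng: np.random.Generator):
        if R < 1:
            raise InvalidInputError("core rank R must be >= 1")
        scale = 1.0 / np.sqrt(R * max(t_q, t_v))
        self.A = Parameter(rng.normal(0.0, scale, size=(t_o, R, t_q)))
        self.B = Parameter(rng.normal(0.0, scale, size=(t_o, R, t_v)))
        self.t_q, self.t_v, self.t_o, self.R = t_q, t_v, t_o, R
        self.training = True

    def dense(self) -> np.ndarray:
        """Materialize the (t_q, t_v, t_o) core (for oracles and export)."""
        return np.einsum("ora,orb->abo", self.A.data, self.B.data)

    def contract(self, qp: Tensor, vp: Tensor) -> Tensor:
        """(B, t_q), (B, t_v) -> (B, t_o) through the factor pairs."""
        b = qp.shape[0]
        a2 = self.A.reshape(self.t_o * self.R, self.t_q).transpose(1, 0)
        b2 = self.B.reshape(self.t_o * self.R, self.t_v).transpose(1, 0)
        s = (qp @ a2) * (vp @ b2)                    # (B, t_o * R)
        return s.reshape(b, self.t_o, self.R).sum(axis=2)


class DenseCore(Module):
    """Unconstrained (t_q, t_v, t_o) core."""

    def __init__(self, t_q: int, t_v: int, t_o: int, rng: np.random.Generator):
        scale = 1.0 / np.sqrt(t_q * t_v)
        self.core = Parameter(rng.normal(0.0, scale, size=(t_q, t_v, t_o)))
        self.t_q, self.t_v, self.t_o = t_q, t_v, t_o
        self.training = True

    def dense(self) -> np.ndarray:
        return self.core.data

    def contract(self, qp: Tensor, vp: Tensor) -> Tensor:
        b = qp.shape[0]
        h = qp @ self.core.reshape(self.t_q, self.t_v * self.t_o)
        h = h.reshape(b, self.t_v, self.t_o)
        return (vp.reshape(b, 1, self.t_v) @ h).reshape(b, self.t_o)


def build_lowrank_core(t_q: int, t_v: int, t_o: int, R: int,
                       seed: int = 0) -> LowRankCore:
    return LowRankCore(t_q, t_v, t_o, R, np.random.default_rng(seed))


class TuckerFusion(Module):
    """Holds W_q, W_v, W_o, the core and bias; fuses pooled question and
    image vectors into answer logits.

    G > 1 concatenates G independent image projections before contraction, so
    the core's image axis has size G * t_v.
    """

    def __init__(self, d_q: int, d_v: int, n_answers: int,
                 t_q: int = 512, t_v: int = 512, t_o: int = 512,
                 R: int | None = 15, G: int = 1, squared: bool = False,
                 rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.d_q, self.d_v, self.n_answers = d_q, d_v, n_answers
        self.t_q, self.t_v, self.t_o, self.G = t_q, t_v, t_o, G
        self.R = R
        self.squared = squared
        self.W_q = Parameter(rng.normal(0.0, np.sqrt(1.0 / d_q), size=(d_q, t_q)))
        self.W_v_glimpses = [
            Parameter(rng.normal(0.0, np.sqrt(1.0 / d_v), size=(d_v, t_v)))
            for _ in range(G)]
        if R is None:
            self.core = DenseCore(t_q, t_v * G, t_o, rng)
        else:
            self.core = LowRankCore(t_q, t_v * G, t_o, R, rng)
        self.W_o = Parameter(rng.normal(0.0, np.sqrt(1.0 / t_o),
                                        size=(t_o, n_answers)))
        self.b_f = Parameter(np.zeros(n_answers))
        self.training = True

    # -- shape helpers -------------------------------------------------------

    @staticmethod
    def _as_batch(x, dim: int, name: str) -> tuple[Tensor, bool]:
        t = as_tensor(x)
        if t.ndim == 1:
            if t.shape[0] != dim:
                raise InvalidInputError(
                    f"{name} has length {t.shape[0]}, expected {dim}")
            return t.reshape(1, dim), True
        if t.shape[-1] != dim:
            raise InvalidInputError(
                f"{name} has trailing dim {t.shape[-1]}, expected {dim}")
        return t, False

    def project_v(self, v: Tensor) -> Tensor:
        parts = [v @ w for w in self.W_v_glimpses]
        return parts[0] if self.G == 1 else concat(parts, axis=-1)

    def __call__(self, q, v, squared: bool | None = None) -> Tensor:
        squared = self.squared if squared is None else squared
        q, was_vec = self._as_batch(q, self.d_q, "question vector")
        v, _ = self._as_batch(v, self.d_v, "image vector")
        qp = q @ self.W_q
        vp = self.project_v(v)
        if squared:
            vp = vp ** 2
        logits = self.core.contract(qp, vp) @ self.W_o + self.b_f
        return logits.reshape(self.n_answers) if was_vec else logits

    # -- reporting -----------------------------------------------------------

    def parameter_counts(self) -> dict[str, int]:
        """Decomposed vs full-tensor parameter counts."""
        return {"decomposed": self.num_parameters(),
                "full_tensor": self.d_q * self.d_v * self.n_answers}


def tucker_fuse(q, v, params: TuckerFusion) -> np.ndarray:
    """Bilinear fusion through the decomposed tensor (no squaring)."""
    return params(q, v, squared=False).data


def squared_tucker_fuse(q, v, params: TuckerFusion) -> np.ndarray:
    """Same pipeline with the projected image vector squared element-wise."""
    return params(q, v, squared=True).data


# ---------------------------------------------------------------------------
# Test oracle: materialize the full tensor
# ---------------------------------------------------------------------------

def full_bilinear_oracle(q, v, params: TuckerFusion,
                         squared: bool = False) -> np.ndarray:
    """Reference logits via the explicitly reconstructed three-way tensor.

    For the plain variant the full d_q x d_v x |A| tensor
    ``T = ((T_c x1 W_q) x2 W_v) x3 W_o`` is built and contracted directly with
    the raw inputs.  For the squared variant the square applies to the
    projected image vector, so the image projection stays outside the
    materialized tensor.  Refuses instances above a size guard.
    """
    q = np.asarray(q, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if q.ndim != 1 or v.ndim != 1:
        raise InvalidInputError("oracle takes single vectors")
    core = params.core.dense()                      # (t_q, G*t_v, t_o)
    w_q = params.W_q.data
    w_v = np.concatenate([w.data for w in params.W_v_glimpses], axis=1)
    w_o = params.W_o.data                           # (t_o, |A|)
    if squared:
        if params.d_q * core.shape[1] * params.n_answers > _ORACLE_GUARD:
            raise InvalidInputError("instance too large for the oracle guard")
        u = np.einsum("abo,da,on->dbn", core, w_q, w_o)
        vp = (v @ w_v) ** 2
        return np.einsum("dbn,d,b->n", u, q, vp) + params.b_f.data
    if params.d_q * params.d_v * params.n_answers > _ORACLE_GUARD:
        raise InvalidInputError("instance too large for the oracle guard")
    full = np.einsum("abo,da,eb,on->den", core, w_q, w_v, w_o)
    return np.einsum("den,d,e->n", full, q, v) + params.b_f.data


# ---------------------------------------------------------------------------
# Baseline fusions
# ---------------------------------------------------------------------------

class BaselineFusion(Module):
    """concat: concatenation + linear; mlb: Hadamard of linear projections;
    mutan: Tucker fusion without the square (same code path)."""

    MODES = ("concat", "mlb", "mutan")

    def __init__(self, mode: str, d_q: int, d_v: int, out_dim: int,
                 rng: np.random.Generator | None = None, **tucker_kwargs):
        if mode not in self.MODES:
            raise InvalidInputError(f"unknown fusion mode {mode!r}")
        rng = rng if rng is not None else np.random.default_rng(0)
        self.mode = mode
        self.d_q, self.d_v, self.out_dim = d_q, d_v, out_dim
        if mode == "concat":
            self.proj = Linear(d_q + d_v, out_dim, rng)
        elif mode == "mlb":
            self.proj_q = Linear(d_q, out_dim, rng, bias=False)
            self.proj_v = Linear(d_v, out_dim, rng, bias=False)
        else:
            self.tucker = TuckerFusion(d_q, d_v, out_dim, squared=False,
                                       rng=rng, **tucker_kwargs)
        self.training = True

    def __call__(self, q, v) -> Tensor:
        q, v = as_tensor(q), as_tensor(v)
        if self.mode == "concat":
            return self.proj(concat([q, v], axis=-1))
        if self.mode == "mlb":
            return self.proj_q(q) * self.proj_v(v)
        return self.tucker(q, v)


def baseline_fuse(q, v, module: BaselineFusion) -> np.ndarray:
    return module(q, v).data


# ---------------------------------------------------------------------------
# Classifier head: z = LN(W_x^T x + W_y^T y); logits = linear(z)
# ---------------------------------------------------------------------------

class ClassifierHead(Module):
    def __init__(self, d: int, n_answers: int, d_z: int = 2048,
                 rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.W_x = Parameter(rng.normal(0.0, np.sqrt(1.0 / d), size=(d, d_z)))
        self.W_y = Parameter(rng.normal(0.0, np.sqrt(1.0 / d), size=(d, d_z)))
        self.ln = LayerNorm(d_z)
        self.out = Linear(d_z, n_answers, rng)
        self.d, self.d_z, self.n_answers = d, d_z, n_answers
        self.training = True

    def fused(self, x, y) -> Tensor:
        x, y = as_tensor(x), as_tensor(y)
        if x.shape[-1] != self.d or y.shape[-1] != self.d:
            raise InvalidInputError(
                f"head expects trailing dim {self.d}, got "
                f"{x.shape[-1]} / {y.shape[-1]}")
        return self.ln(x @ self.W_x + y @ self.W_y)

    def __call__(self, x, y) -> Tensor:
        return self.out(self.fused(x, y))


def classifier_head(x, y, params: ClassifierHead) -> FusionOutput:
    logits = params(x, y).data
    if logits.ndim != 1:
        raise InvalidInputError("classifier_head takes single vectors")
    return FusionOutput.from_logits(logits)
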