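"""End-to-end VQA model: input projections, MCA stack, attended reduction,
and a selectable fusion head over the answer vocabulary."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor
from .coattention import AttendedReduce, AttnConfig, MCAStack
from .errors import InvalidConfigError
from .fusion import BaselineFusion, ClassifierHead, TuckerFusion
from .nn import Linear, Module

__all__ = ["ModelConfig", "VQAModel"]

FUSION_VARIANTS = ("tucker", "tucker_squared", "concat", "mlb", "mutan", "additive")


@dataclass
class ModelConfig:
    n_answers: int = 8
    image_channels: int = 8        # K of the image encoder contract
    question_dim: int = 32         # d of the question encoder
    hidden: int = 512
    heads: int = 8
    L: int = 4
    dropout: float = 0.5
    ffn_mult: int = 4
    fusion_variant: str = "tucker_squared"
    t_q: int = 512
    t_v: int = 512
    t_o: int = 512
    R: int | None = 15
    G: int = 1
    d_z: int = 2048
    seed: int = 0
    swap_ca_roles: bool = False

    def attn(self) -> AttnConfig:
        return AttnConfig(heads=self.heads, hidden=self.hidden,
                          ffn_mult=self.ffn_mult, L=self.L,
                          dropout=self.dropout,
                          swap_ca_roles=self.swap_ca_roles)

    @classmethod
    def tiny(cls, n_answers: int, **overrides) -> "ModelConfig":
        """Desk-scale defaults used throughout the test suite."""
        base = dict(n_answers=n_answers, image_channels=8, question_dim=16,
                    hidden=32, heads=4, L=1, dropout=0.0,
                    t_q=16, t_v=16, t_o=16, R=4, d_z=32)
        base.update(overrides)
        return cls(**base)


class VQAModel(Module):
    def __init__(self, cfg: ModelConfig):
        if cfg.fusion_variant not in FUSION_VARIANTS:
            raise InvalidConfigError(
                f"fusion_variant must be one of {FUSION_VARIANTS}")
        rng = np.random.default_rng(cfg.seed)
        drop_rng = np.random.default_rng([cfg.seed, 1])
        self.cfg = cfg
        h = cfg.hidden
        self.img_proj = Linear(cfg.image_channels, h, rng)
        self.q_proj = Linear(cfg.question_dim, h, rng)
        self.stack = MCAStack(cfg.attn(), rng, drop_rng)
        self.reduce_x = AttendedReduce(h, rng)
        self.reduce_y = AttendedReduce(h, rng)
        v = cfg.fusion_variant
        if v in ("tucker", "tucker_squared", "mutan"):
            self.head = TuckerFusion(
                d_q=h, d_v=h, n_answers=cfg.n_answers,
                t_q=cfg.t_q, t_v=cfg.t_v, t_o=cfg.t_o, R=cfg.R, G=cfg.G,
                squared=(v == "tucker_squared"), rng=rng)
            self.head_out = None
        elif v == "additive":
            self.head = ClassifierHead(h, cfg.n_answers, d_z=cfg.d_z, rng=rng)
            self.head_out = None
        else:
            self.head = BaselineFusion(v, h, h, cfg.d_z, rng)
            self.head_out = Linear(cfg.d_z, cfg.n_answers, rng)
        self.training = True

    def __call__(self, grids: np.ndarray, q_seqs: np.ndarray,
                 q_mask: np.ndarray) -> Tensor:
        """grids: (B, P, K); q_seqs: (B, 26, d); q_mask: (B, 26) -> (B, |A|)."""
        x = self.img_proj(np.asarray(grids, dtype=np.float64))
        y = self.q_proj(np.asarray(q_seqs, dtype=np.float64))
        x, y = self.stack(x, y, x_mask=None, y_mask=np.asarray(q_mask, bool))
        x_vec = self.reduce_x(x)
        y_vec = self.reduce_y(y, mask=np.asarray(q_mask, bool))
        if isinstance(self.head, (TuckerFusion,)):
            return self.head(y_vec, x_vec)           # (q, v) order
        if isinstance(self.head, ClassifierHead):
            return self.head(x_vec, y_vec)
        return self.head_out(self.head(y_vec, x_vec))

    def attention_maps(self) -> list[np.ndarray]:
        return self.stack.attention_maps()

    def parameter_report(self) -> dict[str, int]:
        report = {"total": self.num_parameters()}
        if isinstance(self.head, TuckerFusion):
            report.update(self.head.parameter_counts())
        return report
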