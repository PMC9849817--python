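"""Image-encoder backbones.

Two backbones ship with the package:

``tiny``
    A weight-free, seed-deterministic stand-in for tests: block-mean pools the
    image to ``grid_side x grid_side`` positions and applies a fixed seeded
    random projection to ``output_channels`` channels.

``resnet152``
    The reference 152-layer residual architecture (bottleneck layout
    3-8-36-3), randomly initialized, evaluated in pure NumPy.  On a 448x448
    input it emits a 14x14 grid with 2048 channels.  Pretrained weights are an
    optional plug-in and are never required.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ContractViolationError, InvalidConfigError

__all__ = ["EncoderContract", "get_backbone", "register_backbone",
           "tiny_backbone", "ResNet152"]


@dataclass(frozen=True)
class EncoderContract:
    """Declares what a backbone must emit: a (grid_side^2, K) feature grid."""

    name: str = "tiny"
    output_channels: int = 8
    grid_side: int = 2
    deterministic: bool = True
    seed: int = 0

    @property
    def positions(self) -> int:
        return self.grid_side ** 2


_REGISTRY: dict[str, object] = {}


def register_backbone(name: str, factory) -> None:
    """Register `factory(contract) -> callable(image_chw) -> grid (P, C)`."""
    _REGISTRY[name] = factory


def get_backbone(contract: EncoderContract):
    try:
        factory = _REGISTRY[contract.name]
    except KeyError:
        raise InvalidConfigError(
            f"unknown backbone {contract.name!r}; registered: "
            f"{sorted(_REGISTRY)}") from None
    return factory(contract)


# ---------------------------------------------------------------------------
# tiny: block-mean pooling + fixed random projection
# ---------------------------------------------------------------------------

def tiny_backbone(contract: EncoderContract):
    rng = np.random.default_rng(contract.seed)
    proj = rng.normal(0.0, 1.0, size=(3, contract.output_channels))

    def forward(image: np.ndarray) -> np.ndarray:
        # image: (3, H, W) in [0, 255]
        _, h, w = image.shape
        g = contract.grid_side
        blocks = np.zeros((g * g, 3))
        rows = np.linspace(0, h, g + 1).astype(int)
        cols = np.linspace(0, w, g + 1).astype(int)
        for i in range(g):
            for j in range(g):
                patch = image[:, rows[i]:rows[i + 1], cols[j]:cols[j + 1]]
                blocks[i * g + j] = patch.mean(axis=(1, 2)) / 255.0
        return blocks @ proj

    return forward


# ---------------------------------------------------------------------------
# resnet152: reference architecture, random init, NumPy inference
# ---------------------------------------------------------------------------

def _conv2d(x: np.ndarray, w: np.ndarray, stride: int, pad: int) -> np.ndarray:
    """x: (C, H, W); w: (O, C, kh, kw) -> (O, Ho, Wo).  im2col + GEMM."""
    o, c, kh, kw = w.shape
    if pad:
        x = np.pad(x, ((0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(1, 2))
    win = win[:, ::stride, ::stride]                      # (C, Ho, Wo, kh, kw)
    _, ho, wo, _, _ = win.shape
    cols = win.transpose(1, 2, 0, 3, 4).reshape(ho * wo, c * kh * kw)
    out = cols @ w.reshape(o, -1).T
    return out.T.reshape(o, ho, wo)


def _maxpool(x: np.ndarray, k: int = 3, stride: int = 2, pad: int = 1) -> np.ndarray:
    x = np.pad(x, ((0, 0), (pad, pad), (pad, pad)), constant_values=-np.inf)
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(1, 2))
    return win[:, ::stride, ::stride].max(axis=(3, 4))


def _he(rng, o, c, kh, kw):
    return rng.normal(0.0, np.sqrt(2.0 / (c * kh * kw)),
                      size=(o, c, kh, kw)).astype(np.float32)


class ResNet152:
    """3-8-36-3 bottleneck residual network; inference only.

    Batch-norm runs in inference mode with unit running statistics (identity),
    and the dropout between branch convolutions (rate 1e-4) is inactive at
    inference, so the forward pass is Conv-ReLU chains plus shortcuts.
    """

    BLOCKS = (3, 8, 36, 3)
    WIDTHS = (64, 128, 256, 512)
    EXPANSION = 4

    def __init__(self, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.stem = _he(rng, 64, 3, 7, 7)
        self.stages = []
        in_ch = 64
        for stage, (n_blocks, width) in enumerate(zip(self.BLOCKS, self.WIDTHS)):
            stride = 1 if stage == 0 else 2
            blocks = []
            for b in range(n_blocks):
                s = stride if b == 0 else 1
                out_ch = width * self.EXPANSION
                block = {
                    "conv1": _he(rng, width, in_ch, 1, 1),
                    "conv2": _he(rng, width, width, 3, 3),
                    "conv3": _he(rng, out_ch, width, 1, 1),
                    "stride": s,
                }
                if b == 0:
                    block["down"] = _he(rng, out_ch, in_ch, 1, 1)
                blocks.append(block)
                in_ch = out_ch
            self.stages.append(blocks)
        self.out_channels = in_ch

    def __call__(self, image: np.ndarray) -> np.ndarray:
        """image: (3, H, W) in [0, 255] -> grid (P, 2048)."""
        x = (image.astype(np.float32) / 255.0) - 0.5
        x = np.maximum(_conv2d(x, self.stem, stride=2, pad=3), 0.0)
        x = _maxpool(x)
        for blocks in self.stages:
            for blk in blocks:
                identity = x
                h = np.maximum(_conv2d(x, blk["conv1"], 1, 0), 0.0)
                h = np.maximum(_conv2d(h, blk["conv2"], blk["stride"], 1), 0.0)
                h = _conv2d(h, blk["conv3"], 1, 0)
                if "down" in blk:
                    identity = _conv2d(x, blk["down"], blk["stride"], 0)
                # scale to keep activation variance bounded over 50 blocks
                x = np.maximum(0.5 * (h + identity), 0.0)
        c, hh, ww = x.shape
        return x.reshape(c, hh * ww).T.astype(np.float64)


def _resnet_factory(contract: EncoderContract):
    net = ResNet152(seed=contract.seed)
    if contract.output_channels != net.out_channels:
        raise InvalidConfigError(
            f"resnet152 emits {net.out_channels} channels, contract declares "
            f"{contract.output_channels}")
    return net


register_backbone("tiny", tiny_backbone)
register_backbone("resnet152", _resnet_factory)


def validate_grid(grid: np.ndarray, contract: EncoderContract) -> np.ndarray:
    grid = np.asarray(grid)
    expected = (contract.positions, contract.output_channels)
    if grid.shape != expected:
        raise ContractViolationError(
            f"backbone {contract.name!r} emitted grid {grid.shape}, "
            f"contract requires {expected}")
    return grid
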