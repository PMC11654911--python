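"""U-shaped ConvNeXt encoder-decoder built from a 43-slot channel plan.

The network is a U-Net whose convolutional work is done by ConvNeXt blocks
(7x7 depthwise conv -> channel LayerNorm -> 1x1 expansion -> GELU -> 1x1
projection -> residual).  Every non-depthwise convolution is bound to one of
the 43 tunable slots of a :class:`~lodgeseg.encoding.ChannelPlan`, in plan
order (31 encoder DSCL slots, then 12 decoder USCL slots):

* encoder: 7x7 stem (slot 1); stage 1 with one block (slots 2-3); a 2x2
  stride-2 downsample (slot 4); stage 2 with two blocks (5-8); downsample (9);
  stage 3 with two blocks (10-13); downsample (14); stage 4 with six blocks
  (15-26); downsample (27); bottleneck with two blocks (28-31);
* decoder: four levels of { x2 bilinear upsample, concat with the matching
  encoder feature, 1x1 reduction, one block }, consuming three USCL slots per
  level; a 1x1 head to the 4 class logits (not slot-bound).

With the baseline plan this reproduces the classic doubling/halving channel
profile (32-64-128-256 with 4x block expansion).  Optimized plans decouple the
per-layer counts, so a residual whose input and projection widths differ is
aligned parameter-free (channel crop / zero-pad); no hidden projection layers
enter the cost accounting.

Parameter counts include biases and LayerNorm affine terms; FLOPs are counted
as 2x multiply-accumulates of the convolutions at a reference input size
(bilinear interpolation, normalization and activations are excluded).  These
conventions make cross-plan comparisons meaningful as orderings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .encoding import ChannelPlan, N_SLOTS
from .nn import (
    AdamW,
    BilinearUp2,
    ChannelLayerNorm,
    ConvNeXtBlock,
    DenseConv7,
    Downsample2x2,
    Module,
    PointwiseConv,
)

__all__ = [
    "LayerSpec",
    "ArchitectureSpec",
    "reference_spec",
    "count_parameters",
    "count_flops",
    "tunable_out_channels",
    "SegmentationNet",
    "N_CLASSES",
    "DOWNSAMPLE_FACTOR",
]

N_CLASSES = 4
DOWNSAMPLE_FACTOR = 16  # four stride-2 downsamples

LayerKind = Literal[
    "stem_conv7",
    "downsample",
    "dw_conv7",
    "layer_norm",
    "pw_expand",
    "pw_project",
    "upsample_bilinear",
    "concat_skip",
    "pw_reduce",
    "head_conv",
]

# (slot indices, 0-based into the 43-entry plan)
_STAGE_BLOCK_SLOTS: list[list[tuple[int, int]]] = [
    [(1, 2)],
    [(4, 5), (6, 7)],
    [(9, 10), (11, 12)],
    [(14, 15), (16, 17), (18, 19), (20, 21), (22, 23), (24, 25)],
    [(27, 28), (29, 30)],
]
_DOWNSAMPLE_SLOTS = [3, 8, 13, 26]
_DECODER_SLOTS = [(31, 32, 33), (34, 35, 36), (37, 38, 39), (40, 41, 42)]


@dataclass(frozen=True)
class LayerSpec:
    kind: LayerKind
    in_channels: int
    out_channels: int
    kernel: int = 1
    stride: int = 1
    padding: int = 0
    scale: int = 1  # spatial downscale denominator relative to the input
    tunable_slot: int | None = None


@dataclass(frozen=True)
class ArchitectureSpec:
    layers: tuple[LayerSpec, ...]
    n_classes: int = N_CLASSES
    skip_links: tuple[tuple[int, int], ...] = ()

    def tunable_layers(self) -> list[LayerSpec]:
        return [l for l in self.layers if l.tunable_slot is not None]


def _block_layers(
    c_in: int, c_expand: int, c_out: int, scale: int, slot_expand: int, slot_project: int
) -> list[LayerSpec]:
    return [
        LayerSpec("dw_conv7", c_in, c_in, kernel=7, padding=3, scale=scale),
        LayerSpec("layer_norm", c_in, c_in, scale=scale),
        LayerSpec("pw_expand", c_in, c_expand, scale=scale, tunable_slot=slot_expand),
        LayerSpec("pw_project", c_expand, c_out, scale=scale, tunable_slot=slot_project),
    ]


def reference_spec(plan: ChannelPlan) -> ArchitectureSpec:
    """Deterministic layer table for a plan's optimized channel counts."""
    if len(plan) != N_SLOTS:
        raise ValueError(f"channel plan must have {N_SLOTS} entries, got {len(plan)}")
    c = plan.optimized
    layers: list[LayerSpec] = []
    skip_out_index: list[int] = []  # layer index of each stage's final output
    skip_channels: list[int] = []

    layers.append(LayerSpec("stem_conv7", 3, c[0], kernel=7, padding=3, tunable_slot=0))
    cur = c[0]
    scale = 1
    for stage_idx, blocks in enumerate(_STAGE_BLOCK_SLOTS):
        for se, sp in blocks:
            layers.extend(_block_layers(cur, c[se], c[sp], scale, se, sp))
            cur = c[sp]
        if stage_idx < len(_DOWNSAMPLE_SLOTS):
            skip_out_index.append(len(layers) - 1)
            skip_channels.append(cur)
            sd = _DOWNSAMPLE_SLOTS[stage_idx]
            layers.append(LayerSpec("layer_norm", cur, cur, scale=scale))
            layers.append(
                LayerSpec(
                    "downsample", cur, c[sd], kernel=2, stride=2, scale=scale, tunable_slot=sd
                )
            )
            cur = c[sd]
            scale *= 2

    skip_links: list[tuple[int, int]] = []
    for level, (sr, se, sp) in enumerate(_DECODER_SLOTS):
        scale //= 2
        layers.append(LayerSpec("upsample_bilinear", cur, cur, scale=scale))
        skip_idx = skip_out_index[-1 - level]
        skip_c = skip_channels[-1 - level]
        skip_links.append((skip_idx, len(layers)))
        layers.append(LayerSpec("concat_skip", cur + skip_c, cur + skip_c, scale=scale))
        layers.append(
            LayerSpec("pw_reduce", cur + skip_c, c[sr], scale=scale, tunable_slot=sr)
        )
        layers.extend(_block_layers(c[sr], c[se], c[sp], scale, se, sp))
        cur = c[sp]
    layers.append(LayerSpec("layer_norm", cur, cur, scale=1))
    layers.append(LayerSpec("head_conv", cur, N_CLASSES, scale=1))

    spec = ArchitectureSpec(layers=tuple(layers), skip_links=tuple(skip_links))
    slots = [l.tunable_slot for l in spec.tunable_layers()]
    assert sorted(slots) == list(range(N_SLOTS)), "tunable slots must biject with the plan"
    return spec


def tunable_out_channels(spec: ArchitectureSpec) -> list[int]:
    """Out-channel count of each tunable slot, in plan order."""
    by_slot = {l.tunable_slot: l.out_channels for l in spec.tunable_layers()}
    return [by_slot[i] for i in range(N_SLOTS)]


_PARAM_KINDS = {
    "stem_conv7",
    "downsample",
    "pw_expand",
    "pw_project",
    "pw_reduce",
    "head_conv",
}


def count_parameters(spec: ArchitectureSpec) -> int:
    """Trainable parameters: conv K^2*Cin*Cout + Cout; depthwise K^2*C + C; LN 2C."""
    total = 0
    for l in spec.layers:
        if l.kind in _PARAM_KINDS:
            total += l.kernel * l.kernel * l.in_channels * l.out_channels + l.out_channels
        elif l.kind == "dw_conv7":
            total += l.kernel * l.kernel * l.in_channels + l.in_channels
        elif l.kind == "layer_norm":
            total += 2 * l.in_channels
    return total


def count_flops(spec: ArchitectureSpec, input_hw: tuple[int, int] = (512, 512)) -> float:
    """Convolution FLOPs (2x MAC) for one forward pass at the given input size."""
    h, w = input_hw
    if h % DOWNSAMPLE_FACTOR or w % DOWNSAMPLE_FACTOR:
        raise ValueError(f"input size {input_hw} must be divisible by {DOWNSAMPLE_FACTOR}")
    total = 0.0
    for l in spec.layers:
        if l.kind in _PARAM_KINDS:
            ho, wo = (h // l.scale) // l.stride, (w // l.scale) // l.stride
            total += 2.0 * l.kernel * l.kernel * l.in_channels * l.out_channels * ho * wo
        elif l.kind == "dw_conv7":
            ho, wo = h // l.scale, w // l.scale
            total += 2.0 * l.kernel * l.kernel * l.in_channels * ho * wo
    return total


class SegmentationNet(Module):
    """Trainable network realizing :func:`reference_spec` for a channel plan."""

    def __init__(self, plan: ChannelPlan, seed: int = 0):
        if len(plan) != N_SLOTS:
            raise ValueError(f"channel plan must have {N_SLOTS} entries, got {len(plan)}")
        rng = np.random.default_rng(seed)
        c = plan.optimized
        self.plan = plan
        self.spec = reference_spec(plan)

        self.stem = DenseConv7(3, c[0], rng)
        self.stages: list[list[ConvNeXtBlock]] = []
        self.down_norms: list[ChannelLayerNorm] = []
        self.downs: list[Downsample2x2] = []
        cur = c[0]
        for stage_idx, blocks in enumerate(_STAGE_BLOCK_SLOTS):
            stage = []
            for se, sp in blocks:
                stage.append(ConvNeXtBlock(cur, c[se], c[sp], rng))
                cur = c[sp]
            self.stages.append(stage)
            if stage_idx < len(_DOWNSAMPLE_SLOTS):
                sd = _DOWNSAMPLE_SLOTS[stage_idx]
                self.down_norms.append(ChannelLayerNorm(cur))
                self.downs.append(Downsample2x2(cur, c[sd], rng))
                cur = c[sd]
        self.ups: list[BilinearUp2] = []
        self.reduces: list[PointwiseConv] = []
        self.dec_blocks: list[ConvNeXtBlock] = []
        self._skip_channels = [self.stages[i][-1].c_out for i in range(4)]
        for level, (sr, se, sp) in enumerate(_DECODER_SLOTS):
            skip_c = self._skip_channels[-1 - level]
            self.ups.append(BilinearUp2())
            self.reduces.append(PointwiseConv(cur + skip_c, c[sr], rng))
            self.dec_blocks.append(ConvNeXtBlock(c[sr], c[se], c[sp], rng))
            cur = c[sp]
        self.final_norm = ChannelLayerNorm(cur)
        self.head = PointwiseConv(cur, N_CLASSES, rng)

    def parameters(self):
        params = []
        params.extend(self.stem.parameters())
        for stage in self.stages:
            for block in stage:
                params.extend(block.parameters())
        for norm, down in zip(self.down_norms, self.downs):
            params.extend(norm.parameters())
            params.extend(down.parameters())
        for reduce, block in zip(self.reduces, self.dec_blocks):
            params.extend(reduce.parameters())
            params.extend(block.parameters())
        params.extend(self.final_norm.parameters())
        params.extend(self.head.parameters())
        return params

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Images (B, 3, H, W) in [0, 1] -> logits (B, 4, H, W)."""
        b, c, h, w = x.shape
        if c != 3:
            raise ValueError("expected 3-channel input")
        if h % DOWNSAMPLE_FACTOR or w % DOWNSAMPLE_FACTOR:
            raise ValueError(f"input size ({h},{w}) must be divisible by {DOWNSAMPLE_FACTOR}")
        x = np.ascontiguousarray(x, dtype=np.float32)
        t = self.stem.forward(x)
        skips = []
        for stage_idx, stage in enumerate(self.stages):
            for block in stage:
                t = block.forward(t)
            if stage_idx < len(self.downs):
                skips.append(t)
                t = self.down_norms[stage_idx].forward(t)
                t = self.downs[stage_idx].forward(t)
        self._concat_splits = []
        for level in range(4):
            t = self.ups[level].forward(t)
            skip = skips[-1 - level]
            self._concat_splits.append(t.shape[1])
            t = np.concatenate([t, skip], axis=1)
            t = self.reduces[level].forward(t)
            t = self.dec_blocks[level].forward(t)
        t = self.final_norm.forward(t)
        logits = self.head.forward(t)
        if not np.all(np.isfinite(logits)):
            raise FloatingPointError("non-finite logits in head output")
        return logits

    def backward(self, dlogits: np.ndarray) -> None:
        """Accumulate parameter gradients from the loss gradient w.r.t. logits."""
        d = self.head.backward(np.ascontiguousarray(dlogits, dtype=np.float32))
        d = self.final_norm.backward(d)
        dskips: list[np.ndarray | None] = [None] * 4
        for level in reversed(range(4)):
            d = self.dec_blocks[level].backward(d)
            d = self.reduces[level].backward(d)
            split = self._concat_splits[level]
            d, dskip = d[:, :split], d[:, split:]
            dskips[3 - level] = dskip
            d = self.ups[level].backward(d)
        for stage_idx in reversed(range(len(self.stages))):
            if stage_idx < len(self.downs):
                d = self.downs[stage_idx].backward(d)
                d = self.down_norms[stage_idx].backward(d)
                d = d + dskips[stage_idx]
            for block in reversed(self.stages[stage_idx]):
                d = block.backward(d)
        self.stem.backward(d)

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Per-pixel class labels (B, H, W) by argmax over logits."""
        return np.argmax(self.forward(x), axis=1)

    def make_optimizer(
        self, lr: float = 1.5e-3, weight_decay: float = 5e-5
    ) -> AdamW:
        return AdamW(self.parameters(), lr=lr, weight_decay=weight_decay)
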