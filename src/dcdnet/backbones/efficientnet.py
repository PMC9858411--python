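"""EfficientNet (B0 by default) — MBConv blocks with squeeze-excite and Swish.

The expansion activation of the first block of each stride-2 stage
(``block{N}a_expand_activation``) sits at the incoming scale, mirroring the
Keras layer names used as segmentation skip connections.
"""

from __future__ import annotations

import math

import numpy as np

from ..nn import functional as F
from ..nn.layers import Conv2d, ConvBNAct, Module
from ..nn.tensor import Tensor

# B0 stages: (kernel, stride, expansion, out channels, repeats)
_B0_STAGES = (
    (3, 1, 1, 16, 1),
    (3, 2, 6, 24, 2),
    (5, 2, 6, 40, 2),
    (3, 2, 6, 80, 3),
    (5, 1, 6, 112, 3),
    (5, 2, 6, 192, 4),
    (3, 1, 6, 320, 1),
)
# (width multiplier, depth multiplier) per variant
_VARIANTS = {"b0": (1.0, 1.0), "b1": (1.0, 1.1), "b2": (1.1, 1.2), "b3": (1.2, 1.4)}


def _round_filters(ch: float, width: float, divisor: int = 8) -> int:
    ch *= width
    new = max(divisor, int(ch + divisor / 2) // divisor * divisor)
    if new < 0.9 * ch:
        new += divisor
    return new


class _MBConv(Module):
    def __init__(self, rng, in_ch, kernel, stride, expand, out_ch, se_ratio=0.25):
        super().__init__()
        mid = in_ch * expand
        self.expand = (ConvBNAct(rng, in_ch, mid, 1, act="silu")
                       if expand != 1 else None)
        self.depthwise = ConvBNAct(rng, mid, mid, kernel, stride, act="silu", groups=mid)
        se_ch = max(1, int(in_ch * se_ratio))
        self.se_reduce = Conv2d(rng, mid, se_ch, 1)
        self.se_expand = Conv2d(rng, se_ch, mid, 1)
        self.project = ConvBNAct(rng, mid, out_ch, 1, act="linear")
        self.residual = stride == 1 and in_ch == out_ch

    def forward(self, x):
        h = self.expand(x) if self.expand is not None else x
        expanded = h
        h = self.depthwise(h)
        s = F.sigmoid(self.se_expand(F.silu(self.se_reduce(F.global_avg_pool(h)))))
        h = self.project(F.mul(h, s))
        if self.residual:
            h = F.add(h, x)
        return h, expanded


class EfficientNet(Module):
    TAPS = {
        "Sc0": "top_activation",
        "Sc1": "block6a_expand_activation",
        "Sc2": "block4a_expand_activation",
        "Sc3": "block3a_expand_activation",
        "Sc4": "block2a_expand_activation",
    }

    def __init__(self, rng: np.random.Generator, variant: str = "b0"):
        super().__init__()
        if variant not in _VARIANTS:
            raise ValueError(f"unsupported EfficientNet variant {variant!r}")
        width, depth = _VARIANTS[variant]
        self.variant = variant
        stem_ch = _round_filters(32, width)
        self.stem = ConvBNAct(rng, 3, stem_ch, 3, 2, act="silu")
        blocks, block_ids = [], []
        in_ch = stem_ch
        for stage, (k, s, e, c, n) in enumerate(_B0_STAGES, start=1):
            out_ch = _round_filters(c, width)
            repeats = int(math.ceil(n * depth))
            for r in range(repeats):
                blocks.append(_MBConv(rng, in_ch, k, s if r == 0 else 1, e, out_ch))
                block_ids.append(f"block{stage}{chr(ord('a') + r)}")
                in_ch = out_ch
        self.blocks = blocks
        self._block_ids = block_ids
        top_ch = _round_filters(1280, width)
        self.top = ConvBNAct(rng, in_ch, top_ch, 1, act="silu")
        self.layer_names = (["stem_activation"]
                            + [f"{bid}_expand_activation" for bid in block_ids]
                            + ["top_activation"])

    def forward(self, x: Tensor, record: set[str] | None = None) -> dict[str, Tensor]:
        record = record if record is not None else set(self.TAPS.values())
        acts: dict[str, Tensor] = {}
        h = self.stem(x)
        if "stem_activation" in record:
            acts["stem_activation"] = h
        for bid, blk in zip(self._block_ids, self.blocks):
            h, expanded = blk(h)
            name = f"{bid}_expand_activation"
            if name in record:
                acts[name] = expanded
        h = self.top(h)
        if "top_activation" in record:
            acts["top_activation"] = h
        acts["__out__"] = h
        return acts
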