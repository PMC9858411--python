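"""MobileNetV2 feature extractor (inverted residuals, ReLU6).

Tap points follow the Keras layer naming: the expansion ReLU of the first
block of each stride-2 stage sits at the incoming spatial scale, which makes
``block_N_expand_relu`` the natural skip connection at 1/2 .. 1/16, with the
final 1280-channel activation as the deepest (1/32) feature.
"""

from __future__ import annotations

import numpy as np

from ..nn import functional as F
from ..nn.layers import ConvBNAct, Module
from ..nn.tensor import Tensor

# (expansion t, out channels c, stride s) for blocks 0..16
_BLOCKS = (
    [(1, 16, 1)]
    + [(6, 24, 2), (6, 24, 1)]
    + [(6, 32, 2), (6, 32, 1), (6, 32, 1)]
    + [(6, 64, 2), (6, 64, 1), (6, 64, 1), (6, 64, 1)]
    + [(6, 96, 1), (6, 96, 1), (6, 96, 1)]
    + [(6, 160, 2), (6, 160, 1), (6, 160, 1)]
    + [(6, 320, 1)]
)


class _InvertedResidual(Module):
    def __init__(self, rng, in_ch, t, out_ch, stride):
        super().__init__()
        mid = in_ch * t
        self.expand = ConvBNAct(rng, in_ch, mid, 1, act="relu6") if t != 1 else None
        self.depthwise = ConvBNAct(rng, mid, mid, 3, stride, act="relu6", groups=mid)
        self.project = ConvBNAct(rng, mid, out_ch, 1, act="linear")
        self.residual = stride == 1 and in_ch == out_ch

    def forward(self, x):
        h = self.expand(x) if self.expand is not None else x
        expanded = h
        h = self.project(self.depthwise(h))
        if self.residual:
            h = F.add(h, x)
        return h, expanded


class MobileNetV2(Module):
    TAPS = {
        "Sc0": "out_relu",
        "Sc1": "block_13_expand_relu",
        "Sc2": "block_6_expand_relu",
        "Sc3": "block_3_expand_relu",
        "Sc4": "block_1_expand_relu",
    }

    def __init__(self, rng: np.random.Generator):
        super().__init__()
        self.conv1 = ConvBNAct(rng, 3, 32, 3, 2, act="relu6")
        blocks = []
        in_ch = 32
        for t, c, s in _BLOCKS:
            blocks.append(_InvertedResidual(rng, in_ch, t, c, s))
            in_ch = c
        self.blocks = blocks
        self.conv_last = ConvBNAct(rng, in_ch, 1280, 1, act="relu6")
        self.layer_names = (["Conv1_relu"]
                            + [f"block_{i}_expand_relu" for i in range(1, 17)]
                            + ["out_relu"])

    def forward(self, x: Tensor, record: set[str] | None = None) -> dict[str, Tensor]:
        record = record if record is not None else set(self.TAPS.values())
        acts: dict[str, Tensor] = {}
        h = self.conv1(x)
        for i, blk in enumerate(self.blocks):
            h, expanded = blk(h)
            name = f"block_{i}_expand_relu"
            if name in record:
                acts[name] = expanded
        h = self.conv_last(h)
        if "out_relu" in record or record is None:
            acts["out_relu"] = h
        acts["__out__"] = h
        return acts
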