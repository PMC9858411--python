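"""VGG16 convolutional trunk (13 conv layers, 5 max pools, no classifier head)."""

from __future__ import annotations

import numpy as np

from ..nn import functional as F
from ..nn.layers import Conv2d, Module
from ..nn.tensor import Tensor

_CFG = [(64, 2), (128, 2), (256, 3), (512, 3), (512, 3)]


class VGG16(Module):
    TAPS = {
        "Sc0": "block5_pool",
        "Sc1": "block5_conv3",
        "Sc2": "block4_conv3",
        "Sc3": "block3_conv3",
        "Sc4": "block2_conv2",
    }

    def __init__(self, rng: np.random.Generator):
        super().__init__()
        convs = []
        names = []
        in_ch = 3
        for b, (ch, n) in enumerate(_CFG, start=1):
            for j in range(1, n + 1):
                convs.append(Conv2d(rng, in_ch, ch, 3))
                names.append(f"block{b}_conv{j}")
                in_ch = ch
            names.append(f"block{b}_pool")
        self.convs = convs
        self.layer_names = names

    def forward(self, x: Tensor, record: set[str] | None = None) -> dict[str, Tensor]:
        record = record if record is not None else set(self.TAPS.values())
        acts: dict[str, Tensor] = {}
        h = x
        k = 0
        for b, (ch, n) in enumerate(_CFG, start=1):
            for j in range(1, n + 1):
                h = F.relu(self.convs[k](h))
                k += 1
                name = f"block{b}_conv{j}"
                if name in record:
                    acts[name] = h
            h = F.maxpool2d(h, 2, 2)
            name = f"block{b}_pool"
            if name in record:
                acts[name] = h
        acts["__out__"] = h
        return acts
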