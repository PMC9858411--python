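"""Inception-V3 feature extractor, adapted to 'SAME' padding throughout.

The stock stem uses valid padding, which yields odd intermediate sizes
(299 -> 149 -> 147 ...) and breaks the exact power-of-two scale contract the
decoder relies on. Every convolution and pool here pads 'SAME' so stride-2
stages halve exactly; at 256x512 the taps land on 1/2, 1/4, 1/8, 1/16 and
1/32 like the other backbones. Branch structure and channel counts follow
the standard topology (mixed0..mixed10).
"""

from __future__ import annotations

import numpy as np

from ..nn import functional as F
from ..nn.layers import ConvBNAct, Module
from ..nn.tensor import Tensor


def _cba(rng, in_ch, out_ch, kernel, stride=1):
    return ConvBNAct(rng, in_ch, out_ch, kernel, stride, act="relu")


class _Mixed35(Module):
    """35x35-style block: 1x1 / 5x5 / double-3x3 / pool branches."""

    def __init__(self, rng, in_ch, pool_proj):
        super().__init__()
        self.b0 = _cba(rng, in_ch, 64, 1)
        self.b1a = _cba(rng, in_ch, 48, 1)
        self.b1b = _cba(rng, 48, 64, 5)
        self.b2a = _cba(rng, in_ch, 64, 1)
        self.b2b = _cba(rng, 64, 96, 3)
        self.b2c = _cba(rng, 96, 96, 3)
        self.b3 = _cba(rng, in_ch, pool_proj, 1)

    def forward(self, x):
        return F.concat([
            self.b0(x),
            self.b1b(self.b1a(x)),
            self.b2c(self.b2b(self.b2a(x))),
            self.b3(F.avgpool2d(x, 3, 1, "same")),
        ])


class _Mixed3(Module):
    """Grid reduction 1/8 -> 1/16 (mixed3)."""

    def __init__(self, rng, in_ch):
        super().__init__()
        self.b0 = _cba(rng, in_ch, 384, 3, 2)
        self.b1a = _cba(rng, in_ch, 64, 1)
        self.b1b = _cba(rng, 64, 96, 3)
        self.b1c = _cba(rng, 96, 96, 3, 2)

    def forward(self, x):
        return F.concat([
            self.b0(x),
            self.b1c(self.b1b(self.b1a(x))),
            F.maxpool2d(x, 3, 2, "same"),
        ])


class _Mixed17(Module):
    """17x17-style block with factorised 7x7 branches."""

    def __init__(self, rng, in_ch, c7):
        super().__init__()
        self.b0 = _cba(rng, in_ch, 192, 1)
        self.b1a = _cba(rng, in_ch, c7, 1)
        self.b1b = _cba(rng, c7, c7, (1, 7))
        self.b1c = _cba(rng, c7, 192, (7, 1))
        self.b2a = _cba(rng, in_ch, c7, 1)
        self.b2b = _cba(rng, c7, c7, (7, 1))
        self.b2c = _cba(rng, c7, c7, (1, 7))
        self.b2d = _cba(rng, c7, c7, (7, 1))
        self.b2e = _cba(rng, c7, 192, (1, 7))
        self.b3 = _cba(rng, in_ch, 192, 1)

    def forward(self, x):
        return F.concat([
            self.b0(x),
            self.b1c(self.b1b(self.b1a(x))),
            self.b2e(self.b2d(self.b2c(self.b2b(self.b2a(x))))),
            self.b3(F.avgpool2d(x, 3, 1, "same")),
        ])


class _Mixed8(Module):
    """Grid reduction 1/16 -> 1/32 (mixed8)."""

    def __init__(self, rng, in_ch):
        super().__init__()
        self.b0a = _cba(rng, in_ch, 192, 1)
        self.b0b = _cba(rng, 192, 320, 3, 2)
        self.b1a = _cba(rng, in_ch, 192, 1)
        self.b1b = _cba(rng, 192, 192, (1, 7))
        self.b1c = _cba(rng, 192, 192, (7, 1))
        self.b1d = _cba(rng, 192, 192, 3, 2)

    def forward(self, x):
        return F.concat([
            self.b0b(self.b0a(x)),
            self.b1d(self.b1c(self.b1b(self.b1a(x)))),
            F.maxpool2d(x, 3, 2, "same"),
        ])


class _Mixed9(Module):
    """8x8-style block with split 3x3 branches (mixed9/mixed10)."""

    def __init__(self, rng, in_ch):
        super().__init__()
        self.b0 = _cba(rng, in_ch, 320, 1)
        self.b1a = _cba(rng, in_ch, 384, 1)
        self.b1b = _cba(rng, 384, 384, (1, 3))
        self.b1c = _cba(rng, 384, 384, (3, 1))
        self.b2a = _cba(rng, in_ch, 448, 1)
        self.b2b = _cba(rng, 448, 384, 3)
        self.b2c = _cba(rng, 384, 384, (1, 3))
        self.b2d = _cba(rng, 384, 384, (3, 1))
        self.b3 = _cba(rng, in_ch, 192, 1)

    def forward(self, x):
        h1 = self.b1a(x)
        h2 = self.b2b(self.b2a(x))
        return F.concat([
            self.b0(x),
            F.concat([self.b1b(h1), self.b1c(h1)]),
            F.concat([self.b2c(h2), self.b2d(h2)]),
            self.b3(F.avgpool2d(x, 3, 1, "same")),
        ])


class InceptionV3(Module):
    TAPS = {
        "Sc0": "mixed10",
        "Sc1": "mixed7",
        "Sc2": "mixed2",
        "Sc3": "activation_5",
        "Sc4": "activation_3",
    }

    def __init__(self, rng: np.random.Generator):
        super().__init__()
        self.conv1 = _cba(rng, 3, 32, 3, 2)
        self.conv2 = _cba(rng, 32, 32, 3)
        self.conv3 = _cba(rng, 32, 64, 3)
        self.conv4 = _cba(rng, 64, 80, 1)
        self.conv5 = _cba(rng, 80, 192, 3)
        self.mixed = [
            _Mixed35(rng, 192, 32),   # mixed0 -> 256
            _Mixed35(rng, 256, 64),   # mixed1 -> 288
            _Mixed35(rng, 288, 64),   # mixed2 -> 288
            _Mixed3(rng, 288),        # mixed3 -> 768 @ 1/16
            _Mixed17(rng, 768, 128),  # mixed4
            _Mixed17(rng, 768, 160),  # mixed5
            _Mixed17(rng, 768, 160),  # mixed6
            _Mixed17(rng, 768, 192),  # mixed7
            _Mixed8(rng, 768),        # mixed8 -> 1280 @ 1/32
            _Mixed9(rng, 1280),       # mixed9 -> 2048
            _Mixed9(rng, 2048),       # mixed10 -> 2048
        ]
        self.layer_names = ([f"activation_{i}" for i in range(1, 6)]
                            + [f"mixed{i}" for i in range(11)])

    def forward(self, x: Tensor, record: set[str] | None = None) -> dict[str, Tensor]:
        record = record if record is not None else set(self.TAPS.values())
        acts: dict[str, Tensor] = {}

        def keep(name, t):
            if name in record:
                acts[name] = t
            return t

        h = keep("activation_1", self.conv1(x))
        h = keep("activation_2", self.conv2(h))
        h = keep("activation_3", self.conv3(h))
        h = F.maxpool2d(h, 3, 2, "same")
        h = keep("activation_4", self.conv4(h))
        h = keep("activation_5", self.conv5(h))
        h = F.maxpool2d(h, 3, 2, "same")
        for i, blk in enumerate(self.mixed):
            h = keep(f"mixed{i}", blk(h))
        acts["__out__"] = h
        return acts
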