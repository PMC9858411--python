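"""ResNet50 with pre-activation bottleneck units (MXNet-style naming).

Under this layout ``stage{k}_unit1_relu1`` — the first pre-activation of each
stage — fires *before* the stage's stride-2 convolution, so it exposes the
previous scale: stage2/3/4 taps sit at 1/4, 1/8 and 1/16 while ``relu0``
(after the 7x7 stem) sits at 1/2 and the final post-activation at 1/32.
"""

from __future__ import annotations

import numpy as np

from ..nn import functional as F
from ..nn.layers import BatchNorm2d, Conv2d, Module
from ..nn.tensor import Tensor

_UNITS = (3, 4, 6, 3)
_FILTERS = (64, 128, 256, 512)


class _PreActBottleneck(Module):
    def __init__(self, rng, in_ch: int, f: int, stride: int, downsample: bool):
        super().__init__()
        self.bn1 = BatchNorm2d(in_ch)
        self.conv1 = Conv2d(rng, in_ch, f, 1, bias=False)
        self.bn2 = BatchNorm2d(f)
        self.conv2 = Conv2d(rng, f, f, 3, stride, bias=False)
        self.bn3 = BatchNorm2d(f)
        self.conv3 = Conv2d(rng, f, 4 * f, 1, bias=False)
        self.shortcut = (Conv2d(rng, in_ch, 4 * f, 1, stride, bias=False)
                         if downsample else None)

    def forward(self, x):
        relu1 = F.relu(self.bn1(x))
        h = self.conv1(relu1)
        h = self.conv2(F.relu(self.bn2(h)))
        h = self.conv3(F.relu(self.bn3(h)))
        sc = self.shortcut(relu1) if self.shortcut is not None else x
        return F.add(h, sc), relu1


class ResNet50(Module):
    TAPS = {
        "Sc0": "relu1",
        "Sc1": "stage4_unit1_relu1",
        "Sc2": "stage3_unit1_relu1",
        "Sc3": "stage2_unit1_relu1",
        "Sc4": "relu0",
    }

    def __init__(self, rng: np.random.Generator):
        super().__init__()
        self.conv0 = Conv2d(rng, 3, 64, 7, 2, bias=False)
        self.bn0 = BatchNorm2d(64)
        stages = []
        in_ch = 64
        for k, (units, f) in enumerate(zip(_UNITS, _FILTERS), start=1):
            stage = []
            for u in range(1, units + 1):
                stride = 2 if (u == 1 and k > 1) else 1
                stage.append(_PreActBottleneck(rng, in_ch, f, stride, downsample=u == 1))
                in_ch = 4 * f
            stages.append(stage)
        self.stages = [blk for stage in stages for blk in stage]  # flat for params
        self._stage_sizes = _UNITS
        self.bn1 = BatchNorm2d(in_ch)
        self.layer_names = (["relu0"]
                            + [f"stage{k}_unit{u}_relu1"
                               for k, units in enumerate(_UNITS, start=1)
                               for u in range(1, units + 1)]
                            + ["relu1"])

    def forward(self, x: Tensor, record: set[str] | None = None) -> dict[str, Tensor]:
        record = record if record is not None else set(self.TAPS.values())
        acts: dict[str, Tensor] = {}
        h = F.relu(self.bn0(self.conv0(x)))
        if "relu0" in record:
            acts["relu0"] = h
        h = F.maxpool2d(h, 3, 2, "same")
        i = 0
        for k, units in enumerate(self._stage_sizes, start=1):
            for u in range(1, units + 1):
                h, relu1 = self.stages[i](h)
                i += 1
                name = f"stage{k}_unit{u}_relu1"
                if name in record:
                    acts[name] = relu1
        h = F.relu(self.bn1(h))
        if "relu1" in record:
            acts["relu1"] = h
        acts["__out__"] = h
        return acts
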