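"""DCDNet: encoder-decoder caries segmentation with three sigmoid heads.

The decoder has two parts. The multi-level feature concatenation (MFC)
module walks the encoder pyramid from the deepest map (Sc0, 1/32) upward:
at each of four levels the incoming stream is doubled by a 4x4/stride-2
transposed convolution and merged with a pointwise-projected skip feature;
every merge also emits a 128-channel ConvBNReLU branch that is upsampled to
the 1/2-input scale. The four branches are concatenated into the fused map.
The multi-predicted output (MPO) block then splits that map into three fully
independent convolution+sigmoid paths — one per caries type (occlusal,
proximal, cervical) — so closely related lesion classes cannot compete for
one softmax output.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .backbones import (BackboneSpec, build_backbone_taps,
                        default_backbone_spec, SCALES)
from .errors import AssemblyError, ConfigurationError, ShapeError
from .nn import functional as F
from .nn.layers import Conv2d, ConvBNAct, ConvTranspose2d, Module
from .nn.tensor import Tensor, no_grad

__all__ = ["DCDNetConfig", "DCDNet", "assemble_dcdnet", "forward",
           "mfc_merge_level", "mfc_branch", "shape_ledger", "PredictionSet",
           "SC_CHANNELS"]

# Sc0..Sc4 channel counts at default taps (EfficientNet variant b0)
SC_CHANNELS = {
    "mobilenetv2": (1280, 576, 192, 144, 96),
    "inception-v3": (2048, 768, 288, 192, 64),
    "efficientnet": (1280, 672, 240, 144, 96),
    "resnet50": (2048, 1024, 512, 256, 64),
    "vgg16": (512, 512, 512, 256, 128),
}


@dataclass
class DCDNetConfig:
    backbone: str | BackboneSpec = "resnet50"
    input_h: int = 256
    input_w: int = 512
    merge_channels: int = 256
    branch_channels: int = 128
    head_channels: int = 32
    merge_op: str = "concat"            # 'concat' (layer table) | 'sum' (prose)
    mpo_level4_source: str = "L21"      # 'L21' (symmetric branch) | 'L19' (literal)
    output_upsample: str = "to_input"   # 'to_input' | 'native' (1/2 scale)
    heads: int = 3                      # 1 = single-output ablation
    pretrained: bool = False
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.backbone, str):
            self.backbone = default_backbone_spec(self.backbone,
                                                  pretrained=self.pretrained)
        if min(self.merge_channels, self.branch_channels, self.head_channels) <= 0:
            raise ConfigurationError("channel counts must be positive")
        if self.input_h % 32 or self.input_w % 32:
            raise ConfigurationError("input size must be divisible by 32")
        if self.merge_op not in ("concat", "sum"):
            raise ConfigurationError(f"merge_op {self.merge_op!r} not in (concat, sum)")
        if self.mpo_level4_source not in ("L21", "L19"):
            raise ConfigurationError("mpo_level4_source must be 'L21' or 'L19'")
        if self.output_upsample not in ("to_input", "native"):
            raise ConfigurationError("output_upsample must be 'to_input' or 'native'")
        if self.heads not in (1, 3):
            raise ConfigurationError("heads must be 3 (default) or 1 (ablation)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["backbone"]["tap_names"] = list(d["backbone"]["tap_names"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DCDNetConfig":
        d = dict(d)
        bb = d.pop("backbone")
        spec = BackboneSpec(**bb) if isinstance(bb, dict) else bb
        return cls(backbone=spec, **d)


@dataclass
class PredictionSet:
    """Per-image probability maps, channel order (Type I, Type II, Type III)."""

    maps: np.ndarray  # (3, H, W) in [0, 1]

    def __post_init__(self):
        self.maps = np.asarray(self.maps, dtype=np.float32)
        if self.maps.ndim != 3 or self.maps.shape[0] != 3:
            raise ShapeError(f"PredictionSet wants (3,H,W), got {self.maps.shape}")


# ---------------------------------------------------------------------------
# MFC building blocks
# ---------------------------------------------------------------------------

class _MergeLevel(Module):
    """Pointwise-project the skip feature, then concat (or add) with upstream."""

    def __init__(self, rng, skip_ch: int, merge_channels: int, merge_op: str):
        super().__init__()
        self.pc = Conv2d(rng, skip_ch, merge_channels, 1)
        self.merge_op = merge_op

    def forward(self, upstream: Tensor, skip: Tensor) -> tuple[Tensor, Tensor]:
        pc = self.pc(skip)
        if upstream.shape[2:] != pc.shape[2:]:
            raise ShapeError(
                f"merge: upstream spatial {upstream.shape[2:]} != skip {pc.shape[2:]}")
        if self.merge_op == "sum":
            if upstream.shape[1] != pc.shape[1]:
                raise ShapeError(
                    f"sum merge needs equal channels, got {upstream.shape[1]} "
                    f"and {pc.shape[1]}")
            return F.add(upstream, pc), pc
        return F.concat([upstream, pc]), pc


class _Branch(Module):
    """ConvBNReLU (branch_channels) + nearest upsample to the 1/2-input scale."""

    def __init__(self, rng, in_ch: int, branch_channels: int, factor: int):
        super().__init__()
        if factor < 1 or factor & (factor - 1):
            raise ConfigurationError(f"upsample factor {factor} must be a power of two")
        self.cbr = ConvBNAct(rng, in_ch, branch_channels, 3)
        self.factor = factor

    def forward(self, merged: Tensor) -> tuple[Tensor, Tensor]:
        conv = self.cbr(merged)
        up = F.upsample_nearest(conv, self.factor) if self.factor > 1 else conv
        return up, conv


class _Head(Module):
    """One MPO path: ConvBNReLU(32) then 1x1 conv + sigmoid."""

    def __init__(self, rng, in_ch: int, head_channels: int):
        super().__init__()
        self.cbr = ConvBNAct(rng, in_ch, head_channels, 3)
        self.out = Conv2d(rng, head_channels, 1, 1)

    def forward(self, fused: Tensor) -> Tensor:
        return F.sigmoid(self.out(self.cbr(fused)))


def mfc_merge_level(upstream: Tensor, skip: Tensor, merge_channels: int = 256,
                    merge_op: str = "concat", seed: int = 0) -> Tensor:
    """Functional one-shot merge (fresh pointwise weights drawn from seed)."""
    layer = _MergeLevel(np.random.default_rng(seed), skip.shape[1],
                        merge_channels, merge_op)
    return layer(upstream, skip)[0]


def mfc_branch(merged: Tensor, branch_channels: int = 128,
               upsample_factor: int = 1, seed: int = 0) -> Tensor:
    """Functional one-shot branch (fresh weights drawn from seed)."""
    layer = _Branch(np.random.default_rng(seed), merged.shape[1],
                    branch_channels, upsample_factor)
    return layer(merged)[0]


# ---------------------------------------------------------------------------
# the assembled network
# ---------------------------------------------------------------------------

class DCDNet(Module):
    """Backbone taps -> MFC decoder -> MPO heads, per the layer ledger L0-L28."""

    OUTPUT_NAMES = ("type1", "type2", "type3")

    def __init__(self, config: DCDNetConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        backbone_seed = int(rng.integers(2 ** 31))
        self.taps = build_backbone_taps(config.backbone, config.input_h,
                                        config.input_w, seed=backbone_seed)
        self.backbone = self.taps.module  # expose parameters to Module walk

        mc, bc = config.merge_channels, config.branch_channels
        sc = self._sc_channels()
        self.l1 = Conv2d(rng, sc[0], mc, 1)                  # PC of Sc0
        self.l2 = ConvTranspose2d(rng, mc, mc)               # -> 1/16
        merged_ch = mc if config.merge_op == "sum" else 2 * mc
        self.merges = [_MergeLevel(rng, sc[k], mc, config.merge_op)
                       for k in (1, 2, 3, 4)]
        self.tconvs = [ConvTranspose2d(rng, merged_ch, mc) for _ in range(3)]  # L5,L10,L15
        self.l20 = ConvTranspose2d(rng, merged_ch, mc)       # dead layer; trace only
        self.branches = [_Branch(rng, merged_ch, bc, f) for f in (8, 4, 2, 1)]
        fused_ch = 3 * bc + (bc if config.mpo_level4_source == "L21" else merged_ch)
        self.n_outputs = config.heads
        self.heads = [_Head(rng, fused_ch, config.head_channels)
                      for _ in range(config.heads)]
        self._fused_ch = fused_ch

    def _sc_channels(self) -> tuple[int, ...]:
        spec = self.config.backbone
        key = spec.name
        if key == "efficientnet" and spec.variant != "b0":
            raise ConfigurationError(
                "decoder channel table only ships for EfficientNet-b0")
        return SC_CHANNELS[key]

    # -- forward ----------------------------------------------------------
    def forward(self, x, trace: bool = False):
        """Probability maps for a (B,3,H,W) or (B,H,W) batch.

        Returns a list of `heads` output tensors, or (outputs, activations)
        when trace=True; trace mode also executes the dead layer L20 so the
        full L1-L28 ledger can be checked.
        """
        if not isinstance(x, Tensor):
            x = np.asarray(x, dtype=np.float32)
            if x.ndim == 3:  # grayscale batch -> replicate to 3 channels
                x = np.repeat(x[:, None], 3, axis=1)
            x = Tensor(x)
        if x.shape[1] != 3:
            raise ShapeError(f"expected 3 input channels, got {x.shape[1]}")
        acts: dict[str, Tensor] = {}
        feats = self.taps.forward(x)
        self._check_tap_contract(feats)
        for i, f in enumerate(feats):
            acts[f"Sc{i}"] = f

        h, wd = self.config.input_h, self.config.input_w
        stream = self.l2(self.l1(feats[0]))
        acts["L1"] = self.l1(feats[0]) if trace else None
        acts["L2"] = stream
        branch_outs = []
        merged_last = None
        pc_ids, merge_ids = ("L3", "L8", "L13", "L18"), ("L4", "L9", "L14", "L19")
        cbr_ids, up_ids = ("L6", "L11", "L16", "L21"), ("L7", "L12", "L17", None)
        tconv_ids = ("L5", "L10", "L15")
        for k in range(4):
            merged, pc = self.merges[k](stream, feats[k + 1])
            self._expect(merge_ids[k], merged, (h // SCALES[k + 1], wd // SCALES[k + 1]))
            up, conv = self.branches[k](merged)
            if trace:
                acts[pc_ids[k]] = pc
                acts[merge_ids[k]] = merged
                acts[cbr_ids[k]] = conv
                if up_ids[k]:
                    acts[up_ids[k]] = up
            branch_outs.append(up)
            merged_last = merged
            if k < 3:
                stream = self.tconvs[k](merged)
                if trace:
                    acts[tconv_ids[k]] = stream
        if trace:
            acts["L20"] = self.l20(merged_last)
        if self.config.mpo_level4_source == "L19":
            branch_outs[3] = merged_last
        fused = F.concat(branch_outs)
        self._expect("L22", fused, (h // 2, wd // 2))
        if trace:
            acts["L22"] = fused
        outputs = []
        for i, head in enumerate(self.heads):
            conv = head.cbr(fused)
            out = F.sigmoid(head.out(conv))
            if trace:
                acts[f"L{23 + i}"] = conv
                acts[f"L{26 + i}"] = out
            if self.config.output_upsample == "to_input":
                out = F.upsample_bilinear(out, 2)
            outputs.append(out)
        if trace:
            acts = {k: v for k, v in acts.items() if v is not None}
            return outputs, acts
        return outputs

    def _check_tap_contract(self, feats):
        sizes = [f.shape[2:] for f in feats]
        for i in range(4):
            if (sizes[i][0] * 2, sizes[i][1] * 2) != sizes[i + 1]:
                raise AssemblyError(
                    f"backbone taps violate the doubling contract at Sc{i}->"
                    f"Sc{i + 1}: {sizes}")

    def _expect(self, layer_id, t, hw):
        if t.shape[2:] != hw:
            raise AssemblyError(
                f"{layer_id}: spatial size {t.shape[2:]}, ledger expects {hw}")

    # -- inference convenience ---------------------------------------------
    def predict(self, batch: np.ndarray) -> list[PredictionSet]:
        """Eval-mode forward returning per-image PredictionSets."""
        was_training = self.training
        self.eval()
        try:
            with no_grad():
                outs = self.forward(batch)
        finally:
            self.train(was_training)
        stacked = np.concatenate([o.data for o in outs], axis=1)  # (B,heads,H,W)
        if stacked.shape[1] == 1:
            stacked = np.repeat(stacked, 3, axis=1)  # ablation: union map x3
        return [PredictionSet(m) for m in stacked]


def assemble_dcdnet(config: DCDNetConfig | None = None, **kwargs) -> DCDNet:
    """Compose backbone taps, MFC and MPO into one trainable network."""
    if config is None:
        config = DCDNetConfig(**kwargs)
    return DCDNet(config)


def forward(model: DCDNet, batch: np.ndarray) -> list[PredictionSet]:
    """Batch inference; preserves the batch dimension, never mutates inputs."""
    return model.predict(batch)


# ---------------------------------------------------------------------------
# static shape ledger
# ---------------------------------------------------------------------------

def shape_ledger(config: DCDNetConfig) -> dict[str, tuple[int, int, int]]:
    """Expected (C, H, W) of Sc0..Sc4 and L1..L28, from the layer table alone.

    Independent of the built network: computed from stride/upsampling
    arithmetic so tests can check a traced forward pass against it.
    """
    h, w = config.input_h, config.input_w
    mc, bc, hc = config.merge_channels, config.branch_channels, config.head_channels
    sc = SC_CHANNELS[config.backbone.name if isinstance(config.backbone, BackboneSpec)
                     else config.backbone]
    merged_ch = mc if config.merge_op == "sum" else 2 * mc
    led: dict[str, tuple[int, int, int]] = {}
    for i, s in enumerate(SCALES):
        led[f"Sc{i}"] = (sc[i], h // s, w // s)
    led["L1"] = (mc, h // 32, w // 32)
    led["L2"] = (mc, h // 16, w // 16)
    level = [(("L3", "L4", "L5", "L6", "L7"), 16, 8),
             (("L8", "L9", "L10", "L11", "L12"), 8, 4),
             (("L13", "L14", "L15", "L16", "L17"), 4, 2),
             (("L18", "L19", "L20", "L21", None), 2, 1)]
    for (pc_id, mg_id, tc_id, br_id, up_id), s, f in level:
        led[pc_id] = (mc, h // s, w // s)
        led[mg_id] = (merged_ch, h // s, w // s)
        led[tc_id] = (mc, h // (s // 2), w // (s // 2))
        led[br_id] = (bc, h // s, w // s)
        if up_id:
            led[up_id] = (bc, h // 2, w // 2)
    fused_ch = 3 * bc + (bc if config.mpo_level4_source == "L21" else merged_ch)
    led["L22"] = (fused_ch, h // 2, w // 2)
    for i in range(3):
        led[f"L{23 + i}"] = (hc, h // 2, w // 2)
        led[f"L{26 + i}"] = (1, h // 2, w // 2)
    return led
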