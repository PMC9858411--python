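"""Encoder backbones and their skip-connection tap points.

Five ImageNet-style feature extractors are supported; each exposes five
feature maps Sc0..Sc4 at 1/32, 1/16, 1/8, 1/4 and 1/2 of the input, the
contract the decoder is wired against. Tap layers (skip connections 1-4)
follow the published per-backbone table; Sc0 is the deepest convolutional
feature map, which that table leaves implicit.

Pretrained ImageNet weights require a download this package does not bundle;
construction is always seeded-random unless a weights file is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import ConfigurationError
from ..nn.tensor import Tensor
from .efficientnet import EfficientNet
from .inception import InceptionV3
from .mobilenetv2 import MobileNetV2
from .resnet import ResNet50
from .vgg import VGG16

__all__ = ["BackboneSpec", "BackboneTaps", "build_backbone_taps",
           "default_backbone_spec", "BACKBONE_NAMES", "SCALES"]

_CLASSES = {
    "mobilenetv2": MobileNetV2,
    "inception-v3": InceptionV3,
    "efficientnet": EfficientNet,
    "resnet50": ResNet50,
    "vgg16": VGG16,
}
_ALIASES = {"mobilenet-v2": "mobilenetv2", "mobilenet": "mobilenetv2",
            "inceptionv3": "inception-v3", "inception": "inception-v3",
            "efficientnet-b0": "efficientnet", "resnet-50": "resnet50"}

BACKBONE_NAMES = tuple(_CLASSES)
SCALES = (32, 16, 8, 4, 2)  # spatial reduction of Sc0..Sc4


def _canonical_backbone(name: str) -> str:
    key = name.strip().lower()
    key = _ALIASES.get(key, key)
    if key not in _CLASSES:
        raise ConfigurationError(
            f"unknown backbone {name!r}; supported: {sorted(_CLASSES)}")
    return key


def _normalize_tap(name: str) -> str:
    """Fold printed tap names ('Block 13 expands relu') onto layer names."""
    s = name.strip().lower().replace(" ", "_")
    s = s.replace("expands", "expand")  # published-table typo for MobileNetV2
    return s


@dataclass
class BackboneSpec:
    """Which encoder to build and where to tap it.

    tap_names are skip connections 1-4 (Sc1..Sc4, shallow scale 1/16..1/2);
    deepest_tap is Sc0 (1/32).
    """

    name: str
    tap_names: tuple[str, str, str, str] = ()
    deepest_tap: str = ""
    pretrained: bool = False
    variant: str = "b0"  # EfficientNet only

    def __post_init__(self):
        self.name = _canonical_backbone(self.name)
        cls = _CLASSES[self.name]
        if not self.tap_names:
            self.tap_names = tuple(cls.TAPS[f"Sc{i}"] for i in range(1, 5))
        else:
            self.tap_names = tuple(_normalize_tap(t) for t in self.tap_names)
        if len(self.tap_names) != 4:
            raise ConfigurationError("tap_names must list exactly 4 skip connections")
        if not self.deepest_tap:
            self.deepest_tap = cls.TAPS["Sc0"]
        else:
            self.deepest_tap = _normalize_tap(self.deepest_tap)


def default_backbone_spec(name: str, pretrained: bool = False,
                          variant: str = "b0") -> BackboneSpec:
    return BackboneSpec(name=name, pretrained=pretrained, variant=variant)


@dataclass
class BackboneTaps:
    """A built encoder plus the ordered tap points [Sc0..Sc4]."""

    module: object
    tap_names: list[str] = field(default_factory=list)  # ordered Sc0..Sc4
    scales: tuple[int, ...] = SCALES
    input_hw: tuple[int, int] = (256, 512)

    def forward(self, x, record_all: bool = False) -> list[Tensor]:
        """Feature maps [Sc0..Sc4] for a (B,3,H,W) input."""
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        if x.shape[2:] != self.input_hw:
            raise ConfigurationError(
                f"input spatial size {x.shape[2:]} != built size {self.input_hw}")
        acts = self.module(x, record=set(self.tap_names))
        return [acts[name] for name in self.tap_names]

    def tap_shapes(self) -> list[tuple[int, int]]:
        h, w = self.input_hw
        return [(h // s, w // s) for s in self.scales]


def build_backbone_taps(spec: BackboneSpec | str, input_h: int = 256,
                        input_w: int = 512, seed: int = 0) -> BackboneTaps:
    """Construct a backbone and expose its five tap points.

    Raises ConfigurationError for unknown backbones or indivisible input
    sizes, and an internal consistency error (listing available layers) if a
    requested tap does not exist in the constructed graph.
    """
    if isinstance(spec, str):
        spec = default_backbone_spec(spec)
    if input_h % 32 or input_w % 32 or input_h < 32 or input_w < 32:
        raise ConfigurationError(
            f"input {input_h}x{input_w} must be divisible by 32")
    if spec.pretrained:
        raise ConfigurationError(
            "ImageNet-pretrained weights are not bundled and cannot be "
            "downloaded in this environment; build with pretrained=False and "
            "load weights explicitly via Module.load_state_dict if available")
    rng = np.random.default_rng(seed)
    cls = _CLASSES[spec.name]
    module = cls(rng, variant=spec.variant) if cls is EfficientNet else cls(rng)
    ordered = [spec.deepest_tap, *spec.tap_names]
    available = set(module.layer_names)
    missing = [t for t in ordered if t not in available]
    if missing:
        raise ConfigurationError(
            f"tap(s) {missing} not found in {spec.name}; available layers: "
            f"{sorted(available)}")
    return BackboneTaps(module=module, tap_names=ordered,
                        input_hw=(input_h, input_w))
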