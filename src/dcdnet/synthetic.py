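"""Seeded synthetic panoramic-like fixtures with three lesion classes.

The generator renders a deliberate caricature of a panoramic radiograph — a
dark background with one bright arch of ellipsoidal "teeth" — and plants
three spatially distinct lesion classes on it:

* Type I (occlusal): dark blobs on the biting (top) edge of a tooth;
* Type II (proximal): blobs at the contact point between adjacent teeth;
* Type III (cervical): blobs at the tooth neck, low on the crown.

Lesion counts per image and type are Poisson with means matching the
reference class frequencies (746 : 1627 : 378 labels over 504 images, i.e.
about 1.48 / 3.23 / 0.75 per image). Geometry scales with the canvas, so
the same generator serves the nominal 900x1700 world and the scaled-down
training worlds used on CPU. Every lesion is recorded as a polygon whose
rasterisation is exactly the rendered region, so annotation round trips are
lossless. Output is fully deterministic per (seed, index).

What this does NOT emulate: superimposition artifacts, pulp-chamber
radiolucency, restorations, or real radiographic texture.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from PIL import Image

from .data import (CariesAnnotationSet, Lesion, RadiographImage,
                   rasterize_annotations, write_coco, write_mask_png)

__all__ = ["FixtureSpec", "generate_synthetic_case", "generate_dataset",
           "REFERENCE_LABEL_COUNTS", "REFERENCE_N_IMAGES"]

# published dataset composition the default rates emulate
REFERENCE_LABEL_COUNTS = (746, 1627, 378)
REFERENCE_N_IMAGES = 504
_DEFAULT_RATES = tuple(c / REFERENCE_N_IMAGES for c in REFERENCE_LABEL_COUNTS)


@dataclass
class FixtureSpec:
    n_images: int = 8
    height: int = 900
    width: int = 1700
    n_teeth: tuple[int, int] = (12, 14)          # inclusive range per image
    lesion_rates: tuple[float, float, float] = _DEFAULT_RATES
    lesion_size_px: tuple[int, int] | None = None  # diameter range; None = ~2.2-5.6% of height
    noise_sd: float = 6.0                         # Gaussian, 0-255 intensity units
    seed: int = 0

    def __post_init__(self):
        if min(self.lesion_rates) < 0:
            raise ValueError("lesion rates must be non-negative")
        if self.lesion_size_px is None:
            lo = max(2, round(0.022 * self.height))
            hi = max(lo + 1, round(0.056 * self.height))
            self.lesion_size_px = (lo, hi)
        if self.lesion_size_px[0] < 2:
            raise ValueError("lesions must be at least 2 px across")

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("n_teeth", "lesion_rates", "lesion_size_px"):
            d[key] = list(d[key])
        return d


def _ellipse_polygon(cy, cx, ry, rx, rot, n_pts=24):
    t = np.linspace(0.0, 2.0 * np.pi, n_pts, endpoint=False)
    er, ec = ry * np.sin(t), rx * np.cos(t)
    rows = cy + er * np.cos(rot) + ec * np.sin(rot)
    cols = cx - er * np.sin(rot) + ec * np.cos(rot)
    return np.stack([rows, cols], axis=1)


def _tooth_layout(spec: FixtureSpec, rng) -> list[dict]:
    """Evenly spaced ellipse teeth on a gently curved arch."""
    h, w = spec.height, spec.width
    n = int(rng.integers(spec.n_teeth[0], spec.n_teeth[1] + 1))
    margin = 0.14 * w
    xs = np.linspace(margin, w - margin, n)
    spacing = (xs[1] - xs[0]) if n > 1 else w / 2
    ry = 0.16 * h
    rx = 0.46 * spacing
    teeth = []
    for x in xs:
        arch = 0.06 * h * np.cos((x - w / 2) / (w / 2) * np.pi / 2)
        cy = 0.5 * h - arch + rng.normal(0, 0.01 * h)
        teeth.append({"cy": cy, "cx": x, "ry": ry * rng.uniform(0.9, 1.05),
                      "rx": rx * rng.uniform(0.9, 1.0)})
    return teeth


def _lesion_center(kind: int, teeth: list[dict], rng):
    """A plausible anchor for each lesion class on the rendered arch."""
    if kind == 2 and len(teeth) > 1:
        i = int(rng.integers(0, len(teeth) - 1))
        a, b = teeth[i], teeth[i + 1]
        cy = (a["cy"] + b["cy"]) / 2 + rng.normal(0, 0.15 * a["ry"])
        cx = (a["cx"] + b["cx"]) / 2 + rng.normal(0, 0.1 * a["rx"])
        return cy, cx
    t = teeth[int(rng.integers(0, len(teeth)))]
    if kind == 1:  # occlusal: biting edge
        return (t["cy"] - 0.8 * t["ry"] + rng.normal(0, 0.05 * t["ry"]),
                t["cx"] + rng.uniform(-0.4, 0.4) * t["rx"])
    if kind == 2:  # single tooth fallback
        return t["cy"], t["cx"] + 0.9 * t["rx"]
    # cervical: tooth neck, low on the crown
    return (t["cy"] + 0.7 * t["ry"] + rng.normal(0, 0.05 * t["ry"]),
            t["cx"] + rng.uniform(-0.25, 0.25) * t["rx"])


def generate_synthetic_case(spec: FixtureSpec, index: int
                            ) -> tuple[RadiographImage, CariesAnnotationSet]:
    """Render case `index`: deterministic for a fixed (spec.seed, index)."""
    rng = np.random.default_rng([spec.seed, int(index)])
    h, w = spec.height, spec.width
    img = np.full((h, w), 25.0, dtype=np.float32)
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float32)
    teeth = _tooth_layout(spec, rng)
    for t in teeth:
        inside = (((yy - t["cy"]) / t["ry"]) ** 2
                  + ((xx - t["cx"]) / t["rx"]) ** 2) <= 1.0
        img[inside] = 175.0 + 25.0 * float(rng.uniform())

    image_id = f"case_{index:04d}"
    ann = CariesAnnotationSet(image_id=image_id)
    lo, hi = spec.lesion_size_px
    for kind, rate in zip((1, 2, 3), spec.lesion_rates):
        for _ in range(int(rng.poisson(rate))):
            cy, cx = _lesion_center(kind, teeth, rng)
            a = rng.uniform(lo, hi) / 2.0
            b = rng.uniform(lo, hi) / 2.0
            poly = _ellipse_polygon(cy, cx, a, b, rng.uniform(0, np.pi))
            les = Lesion(type=kind, polygon=poly)
            region = rasterize_annotations(
                CariesAnnotationSet(image_id, [les]), h, w)[kind - 1]
            if not region.any():  # fully off-frame; drop
                continue
            img[region.astype(bool)] *= 0.55  # carious radiolucency: darker
            ann.lesions.append(les)
    img += rng.normal(0.0, spec.noise_sd, size=img.shape).astype(np.float32)
    np.clip(img, 0.0, 255.0, out=img)
    return RadiographImage(pixels=img, source_id=image_id), ann


def generate_dataset(spec: FixtureSpec, out_dir) -> dict:
    """Write a full fixture dataset in the package's on-disk layout.

    Produces images/ (8-bit PNG), masks/ (3-channel PNG), annotations.json
    (COCO-style polygons) and manifest.json recording the spec. Returns the
    manifest dict.
    """
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(exist_ok=True)
    annotations, sizes = [], {}
    total_lesions = 0
    for i in range(spec.n_images):
        img, ann = generate_synthetic_case(spec, i)
        arr = np.round(img.pixels).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(out / "images" / f"{img.source_id}.png")
        mask = rasterize_annotations(ann, img.height, img.width)
        write_mask_png(out / "masks" / f"{img.source_id}.png", mask)
        annotations.append(ann)
        sizes[img.source_id] = (img.height, img.width)
        total_lesions += len(ann.lesions)
    if total_lesions == 0:
        warnings.warn("fixture dataset contains no lesions at the given rates")
    write_coco(out / "annotations.json", annotations, sizes)
    manifest = {
        "format": "dcdnet-fixtures-v1",
        "ids": [a.image_id for a in annotations],
        "n_lesions_per_type": [
            sum(a.counts()[k] for a in annotations) for k in range(3)],
        "spec": spec.to_dict(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
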