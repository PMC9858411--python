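"""Radiograph and annotation IO, preprocessing, and the train/test split.

The preprocessing pipeline mirrors the acquisition geometry of panoramic
radiographs: nominally 900x1700 source images are centre-cropped to 540x1300
(the tooth-bearing middle band) and resized to the 256x512 network input.
Images travel as float32 (H, W) intensity grids; ground truth travels as a
binary (3, H, W) mask tensor with channel order (Type I occlusal, Type II
proximal, Type III cervical). Masks are resized nearest-neighbour and
re-binarised so they stay strictly {0, 1}.

Annotation dialects: per-image 3-channel PNG masks under ``masks/``, or a
COCO-style ``annotations.json`` with polygon segmentations and categories
named type1/type2/type3.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.draw import polygon as draw_polygon
from skimage.transform import resize as _sk_resize

from .errors import ValidationError

__all__ = ["RadiographImage", "Lesion", "CariesAnnotationSet", "DatasetSplit",
           "read_radiograph", "center_crop", "resize_to_input", "resize_mask",
           "rasterize_annotations", "split_dataset", "write_coco", "read_coco",
           "write_mask_png", "read_mask_png", "CariesDataset",
           "INPUT_H", "INPUT_W", "CROP_H", "CROP_W"]

INPUT_H, INPUT_W = 256, 512
CROP_H, CROP_W = 540, 1300
_LUMA = np.array([0.299, 0.587, 0.114], dtype=np.float32)
CATEGORY_NAMES = {1: "type1", 2: "type2", 3: "type3"}
_CATEGORY_IDS = {v: k for k, v in CATEGORY_NAMES.items()}


@dataclass
class RadiographImage:
    """A 2-D intensity raster plus provenance."""

    pixels: np.ndarray  # (H, W) float32
    source_id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValidationError(f"pixels must be a nonempty 2-D grid, "
                                  f"got shape {self.pixels.shape}")
        if not np.isfinite(self.pixels).all():
            raise ValidationError("pixel intensities must be finite")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class Lesion:
    """One annotated carious region: type 1/2/3 plus polygon or mask."""

    type: int  # 1 = occlusal, 2 = proximal, 3 = cervical
    polygon: np.ndarray | None = None  # (N, 2) of (row, col)
    mask: np.ndarray | None = None     # (H, W) bool

    def __post_init__(self):
        if self.polygon is not None:
            self.polygon = np.asarray(self.polygon, dtype=np.float64)
            if self.polygon.ndim != 2 or self.polygon.shape[1] != 2:
                raise ValidationError("lesion polygon must be (N, 2) (row, col)")
        if self.polygon is None and self.mask is None:
            raise ValidationError("lesion needs a polygon or a mask region")


@dataclass
class CariesAnnotationSet:
    image_id: str
    lesions: list[Lesion] = field(default_factory=list)

    def counts(self) -> tuple[int, int, int]:
        """Lesion-label counts per type (the weighted-average weights)."""
        c = [0, 0, 0]
        for les in self.lesions:
            if les.type not in (1, 2, 3):
                raise ValidationError(f"lesion with unknown type {les.type!r} "
                                      f"in image {self.image_id!r}")
            c[les.type - 1] += 1
        return tuple(c)


# ---------------------------------------------------------------------------
# image ops
# ---------------------------------------------------------------------------

def read_radiograph(path) -> RadiographImage:
    """Decode PNG/JPEG/TIFF to a single-channel float32 radiograph.

    Multi-channel input collapses to ITU-R 601 luminance.
    """
    path = Path(path)
    try:
        with Image.open(path) as img:
            arr = np.asarray(img, dtype=np.float32)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read radiograph {path}: {exc}") from exc
    if arr.size == 0:
        raise OSError(f"cannot read radiograph {path}: zero-sized image")
    if arr.ndim == 3:
        arr = arr[..., :3] @ _LUMA
    return RadiographImage(pixels=arr, source_id=path.stem)


def center_crop(img: RadiographImage, target_h: int, target_w: int) -> RadiographImage:
    """Centered window; odd remainders floor (top-left biased)."""
    if target_h < 1 or target_w < 1:
        raise ValueError("crop target must be positive")
    if target_h > img.height or target_w > img.width:
        raise ValueError(f"crop {target_h}x{target_w} exceeds image "
                         f"{img.height}x{img.width}")
    r0 = (img.height - target_h) // 2
    c0 = (img.width - target_w) // 2
    return RadiographImage(pixels=img.pixels[r0:r0 + target_h, c0:c0 + target_w],
                           source_id=img.source_id)


def crop_offsets(h: int, w: int, target_h: int, target_w: int) -> tuple[int, int]:
    return (h - target_h) // 2, (w - target_w) // 2


def resize_to_input(img: RadiographImage, target_h: int = INPUT_H,
                    target_w: int = INPUT_W) -> RadiographImage:
    """Bilinear resize to the network input size."""
    if target_h < 1 or target_w < 1:
        raise ValueError("resize target must be positive")
    if (img.height, img.width) == (target_h, target_w):
        return RadiographImage(img.pixels.copy(), img.source_id)
    out = _sk_resize(img.pixels, (target_h, target_w), order=1,
                     preserve_range=True, anti_aliasing=False)
    return RadiographImage(pixels=out.astype(np.float32), source_id=img.source_id)


def resize_mask(mask: np.ndarray, target_h: int, target_w: int) -> np.ndarray:
    """Nearest-neighbour mask resize, re-binarised to strict {0, 1}."""
    mask = np.asarray(mask)
    if mask.shape[-2:] == (target_h, target_w):
        return (mask > 0).astype(np.uint8)
    chans = mask if mask.ndim == 3 else mask[None]
    out = np.stack([
        _sk_resize(ch.astype(np.float32), (target_h, target_w), order=0,
                   preserve_range=True, anti_aliasing=False)
        for ch in chans])
    out = (out > 0.5).astype(np.uint8)
    return out if mask.ndim == 3 else out[0]


def rasterize_annotations(ann: CariesAnnotationSet, h: int, w: int) -> np.ndarray:
    """Fill each lesion into its type's channel of a (3, h, w) binary tensor.

    Same-type lesions union; different-type overlaps set both channels.
    Regions are clipped to the frame.
    """
    if h < 1 or w < 1:
        raise ValueError("mask size must be positive")
    mask = np.zeros((3, h, w), dtype=np.uint8)
    for i, les in enumerate(ann.lesions):
        if les.type not in (1, 2, 3):
            raise ValidationError(
                f"lesion #{i} of image {ann.image_id!r} has unknown type "
                f"{les.type!r} (expected 1, 2 or 3)")
        if les.mask is not None:
            region = np.asarray(les.mask).astype(bool)
            if region.shape != (h, w):
                raise ValidationError(
                    f"lesion #{i} mask shape {region.shape} != frame {(h, w)}")
            mask[les.type - 1] |= region.astype(np.uint8)
        else:
            rr, cc = draw_polygon(les.polygon[:, 0], les.polygon[:, 1], shape=(h, w))
            mask[les.type - 1, rr, cc] = 1
    return mask


# ---------------------------------------------------------------------------
# dataset split
# ---------------------------------------------------------------------------

@dataclass
class DatasetSplit:
    train_ids: list[str]
    test_ids: list[str]
    seed: int

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(
            {"seed": self.seed, "train_ids": self.train_ids,
             "test_ids": self.test_ids}, indent=2))

    @classmethod
    def from_json(cls, path) -> "DatasetSplit":
        d = json.loads(Path(path).read_text())
        return cls(train_ids=d["train_ids"], test_ids=d["test_ids"], seed=d["seed"])


def split_dataset(ids, train_fraction: float = 0.75, seed: int = 0) -> DatasetSplit:
    """Seeded uniform shuffle; first round(train_fraction * n) ids train."""
    ids = list(ids)
    if not ids:
        raise ValueError("ids must be nonempty")
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate ids in dataset")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    order = np.random.default_rng(seed).permutation(len(ids))
    n_train = int(np.floor(train_fraction * len(ids) + 0.5))
    shuffled = [ids[i] for i in order]
    return DatasetSplit(train_ids=shuffled[:n_train], test_ids=shuffled[n_train:],
                        seed=seed)


# ---------------------------------------------------------------------------
# annotation file dialects
# ---------------------------------------------------------------------------

def write_coco(path, annotations: list[CariesAnnotationSet],
               image_sizes: dict[str, tuple[int, int]]) -> None:
    """COCO-style JSON: images/annotations/categories, polygon segmentation."""
    images, anns = [], []
    image_id_num = {aid: i + 1 for i, aid in enumerate(a.image_id for a in annotations)}
    for ann_set in annotations:
        h, w = image_sizes[ann_set.image_id]
        images.append({"id": image_id_num[ann_set.image_id],
                       "file_name": f"{ann_set.image_id}.png",
                       "height": h, "width": w})
        for les in ann_set.lesions:
            if les.polygon is None:
                raise ValidationError("COCO export needs polygon lesions")
            xy = np.stack([les.polygon[:, 1], les.polygon[:, 0]], axis=1).ravel()
            anns.append({"id": len(anns) + 1,
                         "image_id": image_id_num[ann_set.image_id],
                         "category_id": les.type,
                         "segmentation": [[float(v) for v in xy]]})
    doc = {"images": images, "annotations": anns,
           "categories": [{"id": k, "name": v} for k, v in CATEGORY_NAMES.items()]}
    Path(path).write_text(json.dumps(doc, indent=1))


def read_coco(path) -> dict[str, CariesAnnotationSet]:
    doc = json.loads(Path(path).read_text())
    cat_to_type = {}
    for cat in doc["categories"]:
        name = cat["name"].strip().lower()
        if name not in _CATEGORY_IDS:
            raise ValidationError(f"unknown category {cat['name']!r} "
                                  f"(expected type1/type2/type3)")
        cat_to_type[cat["id"]] = _CATEGORY_IDS[name]
    id_to_stem = {im["id"]: Path(im["file_name"]).stem for im in doc["images"]}
    out = {stem: CariesAnnotationSet(image_id=stem) for stem in id_to_stem.values()}
    for a in doc["annotations"]:
        stem = id_to_stem[a["image_id"]]
        seg = a["segmentation"][0]
        xy = np.asarray(seg, dtype=np.float64).reshape(-1, 2)
        poly = np.stack([xy[:, 1], xy[:, 0]], axis=1)  # (row, col)
        out[stem].lesions.append(Lesion(type=cat_to_type[a["category_id"]],
                                        polygon=poly))
    return out


def write_mask_png(path, mask: np.ndarray) -> None:
    """(3, H, W) binary tensor -> 3-channel PNG with 0/255 values."""
    arr = (np.asarray(mask) > 0).astype(np.uint8) * 255
    Image.fromarray(arr.transpose(1, 2, 0)).save(path)


def read_mask_png(path) -> np.ndarray:
    arr = np.asarray(Image.open(path))
    if arr.ndim != 3 or arr.shape[2] < 3:
        raise ValidationError(f"mask PNG {path} must have 3 channels")
    return (arr[..., :3].transpose(2, 0, 1) > 127).astype(np.uint8)


# ---------------------------------------------------------------------------
# directory-backed dataset
# ---------------------------------------------------------------------------

class CariesDataset:
    """Images + masks from a generated/curated directory, preprocessed.

    Layout: ``root/images/*.png`` plus ``root/annotations.json`` (COCO) or
    ``root/masks/*.png``. Samples come back as (image, mask): image float32
    (H, W) scaled to [0, 1] at ``input_hw``; mask binary (3, H, W) at the
    same size. An optional centre crop (``crop_hw``) precedes the resize.
    """

    def __init__(self, root, ids=None, input_hw=(INPUT_H, INPUT_W), crop_hw=None):
        self.root = Path(root)
        img_dir = self.root / "images"
        if not img_dir.is_dir():
            raise OSError(f"no images/ directory under {self.root}")
        all_ids = sorted(p.stem for p in img_dir.glob("*.png"))
        self.ids = list(ids) if ids is not None else all_ids
        missing = set(self.ids) - set(all_ids)
        if missing:
            raise ValidationError(f"ids without images: {sorted(missing)}")
        self.input_hw = tuple(input_hw)
        self.crop_hw = tuple(crop_hw) if crop_hw else None
        ann_path = self.root / "annotations.json"
        self.annotations = read_coco(ann_path) if ann_path.exists() else None

    def __len__(self) -> int:
        return len(self.ids)

    def _raw(self, image_id: str) -> tuple[RadiographImage, np.ndarray]:
        img = read_radiograph(self.root / "images" / f"{image_id}.png")
        if self.annotations is not None:
            ann = self.annotations.get(image_id, CariesAnnotationSet(image_id))
            mask = rasterize_annotations(ann, img.height, img.width)
        else:
            mask = read_mask_png(self.root / "masks" / f"{image_id}.png")
        return img, mask

    def __getitem__(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        image_id = self.ids[i]
        img, mask = self._raw(image_id)
        if self.crop_hw:
            ch, cw = self.crop_hw
            img = center_crop(img, ch, cw)
            r0, c0 = crop_offsets(*mask.shape[1:], ch, cw)
            mask = mask[:, r0:r0 + ch, c0:c0 + cw]
        th, tw = self.input_hw
        img = resize_to_input(img, th, tw)
        mask = resize_mask(mask, th, tw)
        return img.pixels / 255.0, mask

    @property
    def label_counts(self) -> tuple[int, int, int] | None:
        """Per-type lesion-label counts over the selected ids (COCO only)."""
        if self.annotations is None:
            return None
        totals = np.zeros(3, dtype=int)
        for image_id in self.ids:
            ann = self.annotations.get(image_id)
            if ann is not None:
                totals += np.asarray(ann.counts())
        return tuple(int(v) for v in totals)

    def subset(self, ids) -> "CariesDataset":
        sub = CariesDataset.__new__(CariesDataset)
        sub.__dict__.update(self.__dict__)
        sub.ids = list(ids)
        return sub

    def batches(self, batch_size: int, rng: np.random.Generator | None = None):
        """Yield (images (B,H,W), masks (B,3,H,W)) batches, optionally shuffled."""
        order = np.arange(len(self))
        if rng is not None:
            order = rng.permutation(order)
        for lo in range(0, len(order), batch_size):
            idx = order[lo:lo + batch_size]
            pairs = [self[i] for i in idx]
            yield (np.stack([p[0] for p in pairs]),
                   np.stack([p[1] for p in pairs]))
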