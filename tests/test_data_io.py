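"""Radiograph IO, preprocessing geometry, mask rasterisation and the split."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from PIL import Image

from dcdnet.data import (CariesAnnotationSet, CariesDataset, Lesion,
                         RadiographImage, center_crop, rasterize_annotations,
                         read_coco, read_mask_png, read_radiograph,
                         resize_mask, resize_to_input, split_dataset,
                         write_coco, write_mask_png)
from dcdnet.errors import ValidationError


def _rect(r0, c0, r1, c1):
    """Rectangle polygon (row, col); covers pixels r0..r1-1, c0..c1-1."""
    return np.array([[r0 - 0.5, c0 - 0.5], [r0 - 0.5, c1 - 0.5],
                     [r1 - 0.5, c1 - 0.5], [r1 - 0.5, c0 - 0.5]])


class TestReadRadiograph:
    def test_panoramic_size_preserved(self, tmp_path):
        arr = np.zeros((900, 1700), dtype=np.uint8)
        path = tmp_path / "pano.png"
        Image.fromarray(arr, mode="L").save(path)
        img = read_radiograph(path)
        assert (img.height, img.width) == (900, 1700)
        assert img.source_id == "pano"

    def test_one_pixel_image(self, tmp_path):
        path = tmp_path / "one.png"
        Image.fromarray(np.array([[7]], dtype=np.uint8), mode="L").save(path)
        img = read_radiograph(path)
        assert (img.height, img.width) == (1, 1)
        assert img.pixels[0, 0] == 7

    def test_gray_rgb_collapses_to_same_value(self, tmp_path):
        arr = np.full((4, 5, 3), 128, dtype=np.uint8)
        path = tmp_path / "rgb.png"
        Image.fromarray(arr).save(path)
        img = read_radiograph(path)
        np.testing.assert_allclose(img.pixels, 128.0, atol=1e-4)

    def test_unreadable_file_names_path(self, tmp_path):
        path = tmp_path / "broken.png"
        path.write_bytes(b"not an image")
        with pytest.raises(OSError, match="broken.png"):
            read_radiograph(path)


class TestCenterCrop:
    def test_paper_geometry_offsets(self):
        img = RadiographImage(np.arange(900 * 1700, dtype=np.float32).reshape(900, 1700))
        out = center_crop(img, 540, 1300)
        assert (out.height, out.width) == (540, 1300)
        np.testing.assert_array_equal(out.pixels, img.pixels[180:720, 200:1500])

    def test_identity_when_target_equals_source(self, rng):
        img = RadiographImage(rng.random((10, 12), dtype=np.float32))
        out = center_crop(img, 10, 12)
        np.testing.assert_array_equal(out.pixels, img.pixels)

    def test_floor_rule_on_odd_remainder(self, rng):
        img = RadiographImage(rng.random((5, 5), dtype=np.float32))
        out = center_crop(img, 2, 2)
        np.testing.assert_array_equal(out.pixels, img.pixels[1:3, 1:3])

    def test_oversized_target_rejected(self):
        img = RadiographImage(np.zeros((5, 5), dtype=np.float32))
        with pytest.raises(ValueError):
            center_crop(img, 6, 3)


class TestResize:
    def test_crop_then_resize_pipeline_sizes(self, rng):
        img = RadiographImage(rng.random((900, 1700), dtype=np.float32))
        out = resize_to_input(center_crop(img, 540, 1300))
        assert (out.height, out.width) == (256, 512)

    def test_constant_image_stays_constant(self):
        img = RadiographImage(np.full((54, 130), 3.25, dtype=np.float32))
        out = resize_to_input(img, 25, 51)
        np.testing.assert_allclose(out.pixels, 3.25, rtol=1e-6)

    def test_identity_size(self, rng):
        img = RadiographImage(rng.random((256, 512), dtype=np.float32))
        np.testing.assert_array_equal(resize_to_input(img).pixels, img.pixels)

    def test_determinism(self, rng):
        img = RadiographImage(rng.random((540, 1300), dtype=np.float32))
        a = resize_to_input(center_crop(img, 500, 1200))
        b = resize_to_input(center_crop(img, 500, 1200))
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_mask_resize_preserves_binarity(self, rng):
        mask = (rng.random((3, 96, 192)) > 0.7).astype(np.uint8)
        out = resize_mask(mask, 33, 57)
        assert out.shape == (3, 33, 57)
        assert set(np.unique(out)) <= {0, 1}

    def test_nonpositive_target_rejected(self):
        img = RadiographImage(np.zeros((5, 5), dtype=np.float32))
        with pytest.raises(ValueError):
            resize_to_input(img, 0, 5)


class TestRasterize:
    def test_empty_annotation_all_zero(self):
        mask = rasterize_annotations(CariesAnnotationSet("x"), 7, 9)
        assert mask.shape == (3, 7, 9)
        assert mask.sum() == 0

    def test_full_frame_type2_polygon(self):
        ann = CariesAnnotationSet("x", [Lesion(type=2, polygon=_rect(0, 0, 30, 40))])
        mask = rasterize_annotations(ann, 30, 40)
        assert mask[1].all()
        assert mask[0].sum() == 0 and mask[2].sum() == 0

    def test_cross_type_overlap_sets_both_channels(self):
        ann = CariesAnnotationSet("x", [
            Lesion(type=1, polygon=_rect(2, 2, 8, 8)),
            Lesion(type=3, polygon=_rect(5, 5, 12, 12)),
        ])
        mask = rasterize_annotations(ann, 16, 16)
        overlap = np.zeros((16, 16), bool)
        overlap[5:8, 5:8] = True
        assert mask[0][overlap].all() and mask[2][overlap].all()

    def test_unknown_type_rejected_with_lesion_named(self):
        ann = CariesAnnotationSet("img9", [Lesion(type=4, polygon=_rect(0, 0, 2, 2))])
        with pytest.raises(ValidationError, match="img9"):
            rasterize_annotations(ann, 4, 4)

    def test_matches_pixel_loop_oracle_on_random_rectangles(self, rng):
        """Channel fill equals an exhaustive per-pixel point-in-rect loop."""
        h, w = 21, 33
        lesions, rects = [], []
        for _ in range(12):
            r0, c0 = rng.integers(0, h - 2), rng.integers(0, w - 2)
            r1 = rng.integers(r0 + 1, h + 1)
            c1 = rng.integers(c0 + 1, w + 1)
            t = int(rng.integers(1, 4))
            lesions.append(Lesion(type=t, polygon=_rect(r0, c0, r1, c1)))
            rects.append((t, r0, c0, r1, c1))
        got = rasterize_annotations(CariesAnnotationSet("x", lesions), h, w)
        want = np.zeros((3, h, w), dtype=np.uint8)
        for r in range(h):
            for c in range(w):
                for t, r0, c0, r1, c1 in rects:
                    if r0 <= r < r1 and c0 <= c < c1:
                        want[t - 1, r, c] = 1
        np.testing.assert_array_equal(got, want)


class TestSplit:
    def test_reference_dataset_size(self):
        split = split_dataset([f"im{i}" for i in range(504)], 0.75, seed=1)
        assert len(split.train_ids) == 378
        assert len(split.test_ids) == 126

    def test_determinism(self):
        ids = [f"a{i}" for i in range(17)]
        s1 = split_dataset(ids, seed=5)
        s2 = split_dataset(ids, seed=5)
        assert s1.train_ids == s2.train_ids and s1.test_ids == s2.test_ids

    def test_four_ids_round_to_three_train(self):
        split = split_dataset(list("abcd"), 0.75, seed=0)
        assert len(split.train_ids) == 3 and len(split.test_ids) == 1

    def test_duplicates_rejected(self):
        with pytest.raises(ValidationError):
            split_dataset(["a", "b", "a"])

    @settings(max_examples=25, deadline=None)
    @given(n=st.integers(2, 60), seed=st.integers(0, 2 ** 16),
           frac=st.floats(0.05, 0.95))
    def test_partition_property(self, n, seed, frac):
        ids = [f"id{i}" for i in range(n)]
        split = split_dataset(ids, frac, seed)
        assert set(split.train_ids) | set(split.test_ids) == set(ids)
        assert not set(split.train_ids) & set(split.test_ids)


class TestAnnotationDialects:
    def test_coco_round_trip_rasterises_identically(self, tmp_path):
        lesions = [Lesion(type=2, polygon=_rect(1, 2, 9, 11)),
                   Lesion(type=1, polygon=_rect(4, 4, 6, 19)),
                   Lesion(type=3, polygon=_rect(10, 0, 20, 7))]
        ann = CariesAnnotationSet("case_a", lesions)
        path = tmp_path / "annotations.json"
        write_coco(path, [ann], {"case_a": (24, 32)})
        back = read_coco(path)["case_a"]
        np.testing.assert_array_equal(rasterize_annotations(ann, 24, 32),
                                      rasterize_annotations(back, 24, 32))

    def test_coco_unknown_category_rejected(self, tmp_path):
        doc = {"images": [{"id": 1, "file_name": "x.png", "height": 4, "width": 4}],
               "annotations": [], "categories": [{"id": 1, "name": "molar"}]}
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(doc))
        with pytest.raises(ValidationError):
            read_coco(path)

    def test_mask_png_round_trip(self, tmp_path, rng):
        mask = (rng.random((3, 13, 17)) > 0.6).astype(np.uint8)
        path = tmp_path / "m.png"
        write_mask_png(path, mask)
        np.testing.assert_array_equal(read_mask_png(path), mask)


class TestCariesDataset:
    def test_samples_are_preprocessed(self, fixture_dir):
        root, manifest = fixture_dir
        ds = CariesDataset(root, input_hw=(32, 64))
        assert len(ds) == 8
        image, mask = ds[0]
        assert image.shape == (32, 64) and mask.shape == (3, 32, 64)
        assert 0.0 <= image.min() and image.max() <= 1.0
        assert set(np.unique(mask)) <= {0, 1}

    def test_label_counts_match_manifest(self, fixture_dir):
        root, manifest = fixture_dir
        ds = CariesDataset(root)
        assert list(ds.label_counts) == manifest["n_lesions_per_type"]

    def test_subset_restricts_ids(self, fixture_dir):
        root, _ = fixture_dir
        ds = CariesDataset(root, input_hw=(32, 64))
        sub = ds.subset(ds.ids[:3])
        assert len(sub) == 3
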