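"""Loss and metric arithmetic against hand values and brute-force oracles."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dcdnet.errors import ShapeError, ValidationError
from dcdnet.losses import LossValue, bce_type_loss, total_loss
from dcdnet.metrics import (ConfusionCounts, confusion_counts, evaluate_testset,
                            f1_from_pr, miou, precision_recall_f1,
                            weighted_average)
from dcdnet.nn import Tensor


def _bce_loop(y, p, eps=1e-7):
    """Exhaustive per-pixel reference, independent of the vectorised path."""
    total, n = 0.0, 0
    for yi, pi in zip(np.ravel(y), np.ravel(p)):
        pc = min(max(float(pi), eps), 1 - eps)
        total += -(yi * math.log(pc) + (1 - yi) * math.log(1 - pc))
        n += 1
    return total / n


class TestBceTypeLoss:
    def test_half_probability_gives_ln2(self, rng):
        y = (rng.random((6, 9)) > 0.5).astype(float)
        assert bce_type_loss(y, np.full((6, 9), 0.5)) == pytest.approx(math.log(2))

    def test_perfect_prediction_is_clipped_epsilon(self):
        y = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert bce_type_loss(y, y) <= 1.1e-7

    def test_hand_computed_2x2_case(self):
        y = [[1, 0], [0, 1]]
        p = [[0.9, 0.1], [0.2, 0.8]]
        assert bce_type_loss(y, p) == pytest.approx(0.164252, abs=1e-6)

    def test_tensor_path_matches_numpy_path(self, rng):
        y = (rng.random((3, 5)) > 0.6).astype(np.float32)
        p = rng.random((3, 5)).astype(np.float32)
        t = bce_type_loss(y, Tensor(p))
        assert float(t.data) == pytest.approx(bce_type_loss(y, p), abs=1e-6)

    def test_non_binary_target_rejected(self):
        with pytest.raises(ValidationError):
            bce_type_loss(np.array([[0.5]]), np.array([[0.5]]))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ShapeError):
            bce_type_loss(np.zeros((2, 2)), np.zeros((2, 3)))

    def test_sum_reduction_is_unnormalised(self, rng):
        y = (rng.random((4, 4)) > 0.5).astype(float)
        p = rng.random((4, 4))
        assert bce_type_loss(y, p, "sum") == pytest.approx(
            16 * bce_type_loss(y, p), rel=1e-9)


class TestTotalLoss:
    def test_identical_channels_make_total_equal_per_type(self, rng):
        y1 = (rng.random((1, 1, 4, 4)) > 0.5).astype(float)
        p1 = rng.random((1, 1, 4, 4))
        y = np.repeat(y1, 3, axis=1)
        p = np.repeat(p1, 3, axis=1)
        lv = total_loss(y, p)
        assert lv.total == pytest.approx(lv.per_type[0])

    def test_total_is_mean_of_per_type(self, rng):
        y = (rng.random((2, 3, 4, 4)) > 0.5).astype(float)
        p = rng.random((2, 3, 4, 4))
        lv = total_loss(y, p)
        assert lv.total == pytest.approx(sum(lv.per_type) / 3)
        assert lv.n_types == 3 and lv.n_samples == 2

    def test_matches_pixel_loop_oracle(self, rng):
        for _ in range(10):
            y = (rng.random((2, 3, 4, 4)) > 0.5).astype(float)
            p = rng.random((2, 3, 4, 4))
            lv = total_loss(y, p)
            want = sum(_bce_loop(y[:, k], p[:, k]) for k in range(3)) / 3
            assert lv.total == pytest.approx(want, abs=1e-6)

    def test_wrong_channel_count_rejected(self, rng):
        with pytest.raises(ShapeError):
            total_loss(np.zeros((1, 2, 4, 4)), np.zeros((1, 2, 4, 4)))

    def test_head_list_path_matches_array_path(self, rng):
        y = (rng.random((2, 3, 4, 4)) > 0.5).astype(float)
        p = rng.random((2, 3, 4, 4)).astype(np.float32)
        heads = [Tensor(p[:, k:k + 1]) for k in range(3)]
        tot, report = total_loss(y, heads)
        assert float(tot.data) == pytest.approx(total_loss(y, p).total, abs=1e-6)
        assert isinstance(report, LossValue)


class TestConfusion:
    def test_exact_prediction_has_no_errors(self, rng):
        gt = (rng.random((5, 5)) > 0.5).astype(float)
        c = confusion_counts(gt, gt)
        assert c.fp == 0 and c.fn == 0
        assert c.tp == gt.sum() and c.total == 25

    def test_all_positive_prediction_on_empty_gt(self):
        c = confusion_counts(np.ones((4, 6)), np.zeros((4, 6)))
        assert c.tp == 0 and c.fp == 24 and c.fn == 0 and c.tn == 0

    def test_matches_pixel_loop(self, rng):
        pred = rng.random((3, 3))
        gt = (rng.random((3, 3)) > 0.5).astype(int)
        c = confusion_counts(pred, gt, 0.4)
        tp = fp = fn = tn = 0
        for pi, gi in zip(pred.ravel(), gt.ravel()):
            pb = pi >= 0.4
            tp += pb and gi
            fp += pb and not gi
            fn += (not pb) and gi
            tn += (not pb) and (not gi)
        assert (c.tp, c.fp, c.fn, c.tn) == (tp, fp, fn, tn)

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            confusion_counts(np.zeros((2, 2)), np.zeros((2, 2)), 1.5)

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10 ** 6), t1=st.floats(0.05, 0.95),
           t2=st.floats(0.05, 0.95))
    def test_threshold_monotonicity(self, seed, t1, t2):
        """Raising the threshold never increases the positive count."""
        lo, hi = sorted((t1, t2))
        r = np.random.default_rng(seed)
        pred = r.random((8, 8))
        gt = (r.random((8, 8)) > 0.5).astype(int)
        clo = confusion_counts(pred, gt, lo)
        chi = confusion_counts(pred, gt, hi)
        assert chi.tp + chi.fp <= clo.tp + clo.fp


class TestRatios:
    def test_hand_case(self):
        p, r, f1 = precision_recall_f1(ConfusionCounts(tp=8, fp=2, fn=2, tn=0))
        assert (p, r, f1) == (80.0, 80.0, 80.0)

    def test_zero_tp_degenerates_to_zero(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert precision_recall_f1(ConfusionCounts(0, 0, 0, 9)) == (0, 0, 0)

    def test_balanced_errors_give_fifty(self):
        p, r, f1 = precision_recall_f1(ConfusionCounts(tp=6, fp=6, fn=6))
        assert (p, r, f1) == (50.0, 50.0, 50.0)

    @settings(max_examples=50, deadline=None)
    @given(tp=st.integers(1, 500), fp=st.integers(0, 500), fn=st.integers(0, 500))
    def test_f1_between_precision_and_recall(self, tp, fp, fn):
        """F1 is the harmonic mean, so it sits between P and R (up to one
        float ulp when P == R)."""
        p, r, f1 = precision_recall_f1(ConfusionCounts(tp, fp, fn))
        eps = 1e-9
        assert 0 <= min(p, r) - eps <= f1 <= max(p, r) + eps <= 100 + eps

    @settings(max_examples=40, deadline=None)
    @given(x=st.floats(0.01, 100))
    def test_harmonic_mean_of_equals_is_identity(self, x):
        assert f1_from_pr(x, x) == pytest.approx(x, abs=0.005)

    def test_zero_pair_returns_zero(self):
        assert f1_from_pr(0.0, 0.0) == 0.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            f1_from_pr(120.0, 50.0)


class TestMiou:
    def test_perfect_overlap(self, rng):
        gt = (rng.random((6, 6)) > 0.4).astype(float)
        assert miou(gt, gt) == 100.0

    def test_disjoint_masks(self):
        pred = np.zeros((4, 4))
        pred[:2] = 1
        gt = np.zeros((4, 4))
        gt[2:] = 1
        assert miou(pred, gt) == 0.0

    def test_double_area_superset_gives_fifty(self):
        gt = np.zeros((4, 8))
        gt[:, :2] = 1
        pred = np.zeros((4, 8))
        pred[:, :4] = 1
        assert miou(pred, gt) == 50.0

    def test_empty_union_counts_as_perfect(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert miou(np.zeros((3, 3)), np.zeros((3, 3))) == 100.0


class TestWeightedAverage:
    def test_equal_weights_reduce_to_mean(self):
        assert weighted_average([10, 20, 60], [5, 5, 5]) == pytest.approx(30.0)

    def test_single_nonzero_weight(self):
        assert weighted_average([10, 20, 60], [0, 7, 0]) == 20.0

    def test_reference_label_counts_example(self):
        got = weighted_average([73.45, 66.15, 11.21], [746, 1627, 378])
        assert got == pytest.approx(60.58, abs=0.005)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValidationError):
            weighted_average([1, 2, 3], [0, 0, 0])


class TestEvaluateTestset:
    def _dataset(self, rng, n=4, h=12, w=16):
        images, masks = [], []
        for _ in range(n):
            img = rng.random((h, w)).astype(np.float32)
            mask = (rng.random((3, h, w)) > 0.8).astype(np.uint8)
            images.append(img)
            masks.append(mask)
        return list(zip(images, masks))

    def test_oracle_predictor_scores_100(self, rng):
        data = self._dataset(rng)
        lookup = {id(img): mask for img, mask in data}
        report = evaluate_testset(
            lambda batch: np.stack([lookup[id(img)] for img in
                                    [d[0] for d in data if np.array_equal(d[0], batch[0])]]),
            data)
        for t in report.per_type.values():
            assert all(v == 100.0 for v in t.values())
        assert report.weighted_f1 == 100.0

    def test_all_zero_predictor_scores_0(self, rng):
        data = self._dataset(rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = evaluate_testset(
                lambda batch: np.zeros((1, 3) + batch.shape[-2:]), data)
        for t in report.per_type.values():
            assert t["precision"] == 0 and t["recall"] == 0 and t["f1"] == 0

    def test_micro_report_equals_bruteforce_recomputation(self, rng):
        data = self._dataset(rng)
        predict = lambda batch: np.clip(
            np.stack([m for i, m in data if np.array_equal(i, batch[0])])
            + np.random.default_rng(0).normal(0, 0.3, (1, 3) + batch.shape[-2:]),
            0, 1)
        rng2 = np.random.default_rng(0)
        report = evaluate_testset(predict, data)
        # brute force: pool pixel counts over images with raw loops
        for k, tname in enumerate(("Type I", "Type II", "Type III")):
            tp = fp = fn = 0
            inter = union = 0
            for img, mask in data:
                pred = predict(img[None])[0][k]
                for pv, gv in zip(pred.ravel(), mask[k].ravel()):
                    pb = pv >= 0.5
                    tp += pb and gv
                    fp += pb and not gv
                    fn += (not pb) and gv
            inter, union = tp, tp + fp + fn
            p = 100 * tp / (tp + fp) if tp + fp else 0.0
            r = 100 * tp / (tp + fn) if tp + fn else 0.0
            f1 = 2 * p * r / (p + r) if p + r else 0.0
            got = report.per_type[tname]
            assert got["precision"] == pytest.approx(p)
            assert got["recall"] == pytest.approx(r)
            assert got["f1"] == pytest.approx(f1)
            assert got["miou"] == pytest.approx(100 * inter / union if union else 100)

    def test_empty_test_set_rejected(self):
        with pytest.raises(ValueError):
            evaluate_testset(lambda b: b, [])


class TestReportFiles:
    def test_csv_layout(self, tmp_path, rng):
        data = TestEvaluateTestset()._dataset(rng)
        lookup = [(i, m) for i, m in data]
        report = evaluate_testset(
            lambda batch: np.stack([m for i, m in lookup
                                    if np.array_equal(i, batch[0])]), data)
        csv_path = tmp_path / "metrics.csv"
        report.round(2).to_csv(csv_path, model_name="ResNet50-DCDNet")
        lines = csv_path.read_text().strip().splitlines()
        assert lines[0].split(",")[:2] == ["Model", "Metrics"]
        assert "Type I" in lines[0] and "Type III" in lines[0]
        assert [ln.split(",")[1] for ln in lines[1:]] == [
            "Precision", "Recall", "F1", "mIoU"]

    def test_json_round_trip(self, tmp_path, rng):
        import json
        data = TestEvaluateTestset()._dataset(rng)
        report = evaluate_testset(
            lambda batch: np.stack([m for i, m in data
                                    if np.array_equal(i, batch[0])]), data)
        report.to_json(tmp_path / "metrics.json")
        d = json.loads((tmp_path / "metrics.json").read_text())
        assert d["weighted_f1"] == 100.0
        assert set(d["per_type"]) == {"Type I", "Type II", "Type III"}
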