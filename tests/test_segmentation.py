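"""Segmentation scores, percentile accuracy and map rendering."""

import numpy as np
import pytest

from mcdropconnect import (
    InvalidInputError,
    InvalidParameterError,
    SegmentationBatch,
    confidence_percentile_accuracy,
    render_maps,
    segmentation_scores,
)


def loop_scores(pred, true, n_classes, ignore=None):
    """Per-pixel loop oracle for the confusion-matrix scores."""
    n = np.zeros((n_classes, n_classes))
    for p, t, ig in zip(pred.ravel(), true.ravel(),
                        (ignore if ignore is not None else np.zeros_like(true, bool)).ravel()):
        if not ig:
            n[t, p] += 1
    diag = np.diag(n)
    t_i = n.sum(axis=1)
    present = t_i > 0
    pixel = diag.sum() / t_i.sum()
    mean_acc = np.mean(diag[present] / t_i[present])
    mean_iou = np.mean(diag[present] / (t_i[present] + n.sum(axis=0)[present] - diag[present]))
    return pixel, mean_acc, mean_iou


class TestSegmentationScores:
    def test_perfect_prediction_scores_one(self):
        lab = np.array([[0, 1], [2, 1]])
        s = segmentation_scores(SegmentationBatch(lab, lab, n_classes=3))
        assert s == (1.0, 1.0, 1.0)

    def test_hand_computed_two_class_confusion(self):
        true = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        pred = np.array([0, 0, 0, 1, 1, 1, 1, 0])  # confusion [[3,1],[1,3]]
        s = segmentation_scores(SegmentationBatch(pred, true, n_classes=2))
        assert s.pixel_accuracy == pytest.approx(0.75)
        assert s.mean_accuracy == pytest.approx(0.75)
        assert s.mean_iou == pytest.approx(0.6)

    def test_class_absent_from_ground_truth_excluded_from_means(self):
        true = np.array([0, 0, 1, 1])
        pred = np.array([0, 0, 1, 2])  # class 2 never in ground truth
        s = segmentation_scores(SegmentationBatch(pred, true, n_classes=3))
        assert s.mean_accuracy == pytest.approx((1.0 + 0.5) / 2)

    def test_matches_per_pixel_loop_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            c = rng.integers(2, 5)
            true = rng.integers(0, c, size=(6, 7))
            pred = rng.integers(0, c, size=(6, 7))
            s = segmentation_scores(SegmentationBatch(pred, true, n_classes=c))
            ref = loop_scores(pred, true, c)
            np.testing.assert_allclose(s, ref, atol=1e-12)

    def test_ignore_label_excluded_from_counts(self):
        true = np.array([[0, 255], [1, 1]])
        pred = np.array([[0, 0], [0, 1]])
        s = segmentation_scores(SegmentationBatch(pred, true, n_classes=2))
        ref = loop_scores(pred, true, 2, ignore=(true == 255))
        np.testing.assert_allclose(s, ref, atol=1e-12)

    def test_all_pixels_ignored_rejected(self):
        full = np.full((2, 2), 255)
        with pytest.raises(InvalidInputError):
            segmentation_scores(SegmentationBatch(full, full, n_classes=2))

    def test_out_of_range_labels_rejected(self):
        with pytest.raises(InvalidInputError):
            SegmentationBatch(np.zeros((2, 2), int), np.full((2, 2), 7), n_classes=3)


class TestPercentileAccuracy:
    def test_percentile_zero_scores_all_pixels(self):
        u = np.linspace(0, 1, 10)
        correct = u < 0.5
        assert confidence_percentile_accuracy(u, correct, 0) == pytest.approx(0.5)

    def test_enumeration_example(self):
        u = np.arange(10) / 10
        correct = u < 0.5
        assert confidence_percentile_accuracy(u, correct, 50) == 1.0

    def test_percentile_90_retains_ten_percent(self):
        u = np.arange(10) / 10
        correct = u < 0.1
        assert confidence_percentile_accuracy(u, correct, 90) == 1.0  # only u=0 kept

    def test_percentile_loop_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = rng.integers(5, 60)
            u = rng.random(n)
            correct = rng.random(n) < 0.6
            q = float(rng.choice([0, 10, 25, 50, 75, 90]))
            m = int(np.ceil((1 - q / 100) * n - 1e-12))
            kept = sorted(range(n), key=lambda i: (u[i], i))[:m]
            expected = np.mean([correct[i] for i in kept])
            assert confidence_percentile_accuracy(u, correct, q) == pytest.approx(expected)

    def test_invalid_percentile_rejected(self):
        with pytest.raises(InvalidParameterError):
            confidence_percentile_accuracy([0.5], [True], 100)


class TestRenderMaps:
    def test_perfect_certain_maps_are_white(self):
        lab = np.zeros((4, 4), int)
        batch = SegmentationBatch(lab, lab, n_classes=2)
        corr, conf = render_maps(batch, np.zeros((4, 4)), threshold=1.0)
        assert np.all(np.asarray(corr) == 255) and np.all(np.asarray(conf) == 255)

    def test_zero_threshold_confidence_map_all_black(self):
        lab = np.zeros((3, 3), int)
        batch = SegmentationBatch(lab, lab, n_classes=2)
        _, conf = render_maps(batch, np.zeros((3, 3)), threshold=0.0)
        assert np.all(np.asarray(conf) == 0)

    def test_white_pixels_equal_correct_count(self):
        rng = np.random.default_rng(2)
        true = rng.integers(0, 3, size=(8, 8))
        pred = rng.integers(0, 3, size=(8, 8))
        batch = SegmentationBatch(pred, true, n_classes=3)
        corr, _ = render_maps(batch, np.zeros((8, 8)), threshold=0.5)
        assert np.sum(np.asarray(corr) == 255) == np.sum(pred == true)

    def test_uncertainty_heat_map_export(self, tmp_path):
        from mcdropconnect import save_uncertainty_map
        u = np.random.default_rng(3).random((6, 6))
        save_uncertainty_map(u, tmp_path / "unc")
        with np.load(tmp_path / "unc.npz") as d:
            assert d["i_norm"].dtype == np.float32
            np.testing.assert_allclose(d["i_norm"], u, atol=1e-6)
        assert (tmp_path / "unc.png").stat().st_size > 0

    def test_nifti_volume_loads_as_slices(self, tmp_path):
        nib = pytest.importorskip("nibabel")
        from mcdropconnect import load_nifti_slices
        vol = np.random.default_rng(4).integers(0, 3, size=(5, 6, 7)).astype(np.int16)
        path = tmp_path / "vol.nii"
        nib.save(nib.Nifti1Image(vol, np.eye(4)), path)
        slices = load_nifti_slices(path)
        assert slices.shape == (7, 5, 6)
        np.testing.assert_array_equal(slices[0], vol[:, :, 0])

    def test_ignored_pixels_render_gray(self):
        true = np.array([[0, 255], [1, 0]])
        pred = np.array([[0, 0], [1, 0]])
        batch = SegmentationBatch(pred, true, n_classes=2)
        corr, conf = render_maps(batch, np.zeros((2, 2)), threshold=0.5)
        assert np.asarray(corr)[0, 1] == 127 and np.asarray(conf)[0, 1] == 127
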