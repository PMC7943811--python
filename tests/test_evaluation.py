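"""Correctness x certainty confusion, ratio metrics, curves, KS separation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mcdropconnect import (
    ConfusionCounts,
    InvalidInputError,
    InvalidParameterError,
    ShapeMismatchError,
    ThresholdEvaluation,
    certainty_split,
    confusion_counts,
    correctness_map,
    ks_separation,
    metric_curves,
    ratio_metrics,
)
from mcdropconnect.evaluation import auc_percent


def brute_force_counts(i_norm, correct, tau):
    """Per-item loop oracle for the confusion at one threshold."""
    n_cc = n_ic = n_cu = n_iu = 0
    for u, c in zip(i_norm, correct):
        certain = u < tau
        if c and certain:
            n_cc += 1
        elif not c and certain:
            n_ic += 1
        elif c:
            n_cu += 1
        else:
            n_iu += 1
    return ConfusionCounts(n_cc, n_ic, n_cu, n_iu)


class TestCorrectnessAndCertainty:
    def test_correctness_elementwise(self):
        np.testing.assert_array_equal(correctness_map([1, 2, 3], [1, 0, 3]),
                                      [True, False, True])
        assert correctness_map([1, 2], [1, 2]).all()
        assert not correctness_map([1, 2], [3, 4]).any()

    def test_correctness_shape_mismatch(self):
        with pytest.raises(ShapeMismatchError):
            correctness_map([1, 2], [1, 2, 3])

    def test_threshold_one_makes_everything_below_certain(self):
        assert certainty_split([0.0, 0.5, 0.99], 1.0).all()

    def test_threshold_zero_makes_nothing_certain(self):
        assert not certainty_split([0.0, 0.5, 1.0], 0.0).any()

    def test_tie_at_threshold_counts_as_uncertain(self):
        np.testing.assert_array_equal(certainty_split([0.1, 0.5, 0.9], 0.5),
                                      [True, False, False])

    def test_threshold_out_of_range(self):
        with pytest.raises(InvalidParameterError):
            certainty_split([0.5], 1.5)


class TestConfusionAndRatios:
    def test_all_correct_certain(self):
        c = confusion_counts([True] * 5, [True] * 5)
        assert c == (5, 0, 0, 0)

    def test_enumeration_of_all_four_cells(self):
        c = confusion_counts([True, True, False, False], [True, False, True, False])
        assert c == (1, 1, 1, 1)

    @given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=1, max_size=60))
    def test_counts_partition_the_items(self, pairs):
        correct, certain = zip(*pairs)
        assert confusion_counts(correct, certain).total == len(pairs)

    def test_ratio_formulas(self):
        r = ratio_metrics(ConfusionCounts(90, 10, 5, 20))
        assert r.r_cc == pytest.approx(0.9)
        assert r.r_iu == pytest.approx(20 / 30)
        assert r.ua == pytest.approx(110 / 125)

    def test_perfect_case_has_undefined_r_iu(self):
        r = ratio_metrics(ConfusionCounts(10, 0, 0, 0))
        assert r.r_cc == 1.0 and r.ua == 1.0 and np.isnan(r.r_iu)

    def test_all_uncertain_has_undefined_r_cc(self):
        r = ratio_metrics(ConfusionCounts(0, 0, 3, 2))
        assert np.isnan(r.r_cc) and r.r_iu == 1.0

    def test_zero_counts_rejected(self):
        with pytest.raises(InvalidInputError):
            ratio_metrics(ConfusionCounts(0, 0, 0, 0))

    def test_threshold_evaluation_constructor(self):
        ev = ThresholdEvaluation.at([0.1, 0.9], [True, False], 0.5)
        assert ev.counts == (1, 0, 0, 1) and ev.ratios.ua == 1.0


class TestMetricCurves:
    def test_vectorised_sweep_matches_bruteforce_loop(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = rng.integers(1, 40)
            i_norm = np.round(rng.random(n), 2)
            correct = rng.random(n) < 0.7
            out = metric_curves(i_norm, correct, thresholds=np.linspace(0, 1, 11))
            for _, row in out.table.iterrows():
                ref = brute_force_counts(i_norm, correct, row["threshold"])
                assert (row["n_cc"], row["n_ic"], row["n_cu"], row["n_iu"]) == tuple(ref)

    def test_constant_metric_gives_auc_100(self):
        # all-correct items, all certain for every positive threshold
        out = metric_curves(np.zeros(10), np.ones(10, dtype=bool))
        assert out.auc["r_cc"] == pytest.approx(100.0)

    def test_linear_ramp_gives_auc_50(self):
        grid = np.linspace(0, 1, 101)
        assert auc_percent(grid, grid.copy(), 0.0) == pytest.approx(50.0)

    def test_auc_stable_under_grid_refinement(self):
        rng = np.random.default_rng(1)
        i_norm = rng.beta(2, 3, size=400)
        i_norm = (i_norm - i_norm.min()) / (i_norm.max() - i_norm.min())
        correct = rng.random(400) < (1 - 0.6 * i_norm)
        coarse = metric_curves(i_norm, correct, np.linspace(0, 1, 101))
        fine = metric_curves(i_norm, correct, np.linspace(0, 1, 1001))
        for name in ("r_cc", "r_iu", "ua"):
            assert coarse.auc[name] == pytest.approx(fine.auc[name], abs=0.5)

    def test_counts_sum_to_n_at_every_threshold(self):
        rng = np.random.default_rng(2)
        i_norm = rng.random(57)
        correct = rng.random(57) < 0.5
        table = metric_curves(i_norm, correct).table
        np.testing.assert_array_equal(
            table[["n_cc", "n_ic", "n_cu", "n_iu"]].sum(axis=1), 57)

    def test_full_threshold_recovers_prediction_accuracy(self):
        # at I_T = 1 with all i_norm < 1: R_cc = UA = accuracy, R_iu = 0
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = rng.integers(2, 50)
            i_norm = rng.random(n) * 0.99
            correct = rng.random(n) < 0.6
            if not correct.any() or correct.all():
                continue
            row = metric_curves(i_norm, correct).table.iloc[-1]
            acc = correct.mean()
            assert row["r_cc"] == pytest.approx(acc)
            assert row["ua"] == pytest.approx(acc)
            assert row["r_iu"] == 0.0

    def test_bad_grid_rejected(self):
        with pytest.raises(InvalidParameterError):
            metric_curves([0.5], [True], thresholds=[0.0, 0.5])
        with pytest.raises(InvalidParameterError):
            metric_curves([0.5], [True], thresholds=[0.0, 0.5, 0.5, 1.0])


class TestKSSeparation:
    def test_identical_groups_have_zero_distance(self):
        d, _ = ks_separation([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert d == 0.0

    def test_disjoint_supports_have_distance_one(self):
        d, p = ks_separation([0.0, 0.1], [0.8, 0.9])
        assert d == 1.0 and p < 0.5

    def test_cdf_enumeration_example(self):
        d, _ = ks_separation([0, 0, 1, 1], [1, 1])
        assert d == pytest.approx(0.5)

    def test_empty_group_rejected(self):
        with pytest.raises(InvalidInputError):
            ks_separation([], [0.5])
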