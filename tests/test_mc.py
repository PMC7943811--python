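"""Monte Carlo prediction engine: aggregation, seeding, convergence."""

import numpy as np
import pytest

from mcdropconnect import (
    InvalidInputError,
    InvalidParameterError,
    MCPredictionSet,
    StreamingMC,
    convergence_curve,
    deterministic_predict,
    mc_predict,
    predicted_labels,
    predictive_mean,
    tiny_mlp,
)
from mcdropconnect.nn import Network, ReLU


class TestPredictiveMean:
    def test_mean_of_opposite_point_masses_is_uniform(self):
        mcset = MCPredictionSet(samples=np.array([[[1.0, 0.0]], [[0.0, 1.0]]]))
        np.testing.assert_allclose(predictive_mean(mcset), [[0.5, 0.5]])

    def test_identical_samples_are_a_fixed_point(self):
        s = np.tile([[0.2, 0.3, 0.5]], (7, 1, 1))
        np.testing.assert_allclose(predictive_mean(MCPredictionSet(samples=s)),
                                   [[0.2, 0.3, 0.5]])

    def test_three_sample_mean(self):
        s = np.array([[[0.9, 0.1]], [[0.6, 0.4]], [[0.6, 0.4]]])
        np.testing.assert_allclose(predictive_mean(MCPredictionSet(samples=s)),
                                   [[0.7, 0.3]])

    def test_rows_remain_on_the_simplex(self):
        rng = np.random.default_rng(0)
        s = rng.dirichlet(np.ones(4), size=(20, 30)).reshape(20, 30, 4)
        mean = predictive_mean(MCPredictionSet(samples=s))
        np.testing.assert_allclose(mean.sum(axis=-1), 1.0, atol=1e-6)

    def test_argmax_ties_break_to_lowest_class(self):
        assert predicted_labels(np.array([[0.4, 0.4, 0.2]]))[0] == 0


class TestMCPredict:
    def test_keep_prob_one_matches_deterministic_pass_exactly(self):
        net = tiny_mlp(keep_prob=1.0, seed=1)
        x = np.random.default_rng(1).normal(size=(10, 8))
        mcset = mc_predict(net, x, T=5, seed=0)
        det = deterministic_predict(net, x)
        for t in range(5):
            np.testing.assert_array_equal(mcset.samples[t], det)

    def test_fixed_seed_reproduces_samples_bitwise(self):
        net = tiny_mlp(seed=2)
        x = np.random.default_rng(2).normal(size=(6, 8))
        a = mc_predict(net, x, T=8, seed=5)
        b = mc_predict(net, x, T=8, seed=5)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_continued_stream_equals_single_longer_run(self):
        net = tiny_mlp(seed=3)
        x = np.random.default_rng(3).normal(size=(4, 8))
        full = mc_predict(net, x, T=7, seed=9)
        first = mc_predict(net, x, T=3, seed=9)
        rest = mc_predict(net, x, T=4, seed=9, start_index=3)
        np.testing.assert_array_equal(np.concatenate([first.samples, rest.samples]),
                                      full.samples)

    def test_model_without_stochastic_layers_warns(self):
        net = Network([ReLU()], seed=0)
        x = np.abs(np.random.default_rng(4).normal(size=(3, 2)))
        with pytest.warns(UserWarning):
            mcset = mc_predict(net, x, T=3, seed=0)
        np.testing.assert_array_equal(mcset.samples[0], mcset.samples[2])

    def test_invalid_T_rejected(self):
        with pytest.raises(InvalidParameterError):
            mc_predict(tiny_mlp(seed=0), np.zeros((1, 8)), T=0, seed=0)

    def test_sample_rows_validated_on_construction(self):
        with pytest.raises(InvalidInputError):
            MCPredictionSet(samples=np.full((2, 3, 2), 0.9))

    def test_save_load_roundtrip(self, tmp_path):
        net = tiny_mlp(seed=4)
        x = np.random.default_rng(5).normal(size=(5, 8))
        mcset = mc_predict(net, x, T=4, seed=1)
        path = tmp_path / "preds.npz"
        mcset.save(path, manifest={"seed": 1})
        loaded = MCPredictionSet.load(path)
        np.testing.assert_array_equal(loaded.samples, mcset.samples)
        assert (tmp_path / "preds.npz.manifest.json").exists()


class TestStreamingAccumulator:
    def test_equivalent_to_full_storage(self):
        rng = np.random.default_rng(6)
        samples = rng.dirichlet(np.ones(3), size=(15, 9)).reshape(15, 9, 3)
        acc = StreamingMC()
        for t in range(15):
            acc.update(samples[t])
        from mcdropconnect import mutual_information
        np.testing.assert_allclose(acc.mean, samples.mean(axis=0), atol=1e-12)
        np.testing.assert_allclose(acc.mutual_information(),
                                   mutual_information(samples), atol=1e-10)


class TestConvergenceCurve:
    def test_deterministic_model_has_constant_error_and_zero_std(self, quick_classifier):
        res, xte, yte = quick_classifier
        net = tiny_mlp(keep_prob=1.0, seed=1)
        df = convergence_curve(net, xte[:50], yte[:50], [1, 2, 4], repetitions=3, seed=0)
        assert df["error_mean"].nunique() == 1
        np.testing.assert_array_equal(df["error_std"], 0.0)

    def test_std_shrinks_with_T_on_trained_model(self, quick_classifier):
        res, xte, yte = quick_classifier
        df = convergence_curve(res.network, xte[:100], yte[:100], [2, 64],
                               repetitions=10, seed=3)
        assert df["error_std"].iloc[-1] <= df["error_std"].iloc[0]

    def test_summary_statistics_reported(self, quick_classifier):
        res, xte, yte = quick_classifier
        df = convergence_curve(res.network, xte[:100], yte[:100], [1, 4, 16],
                               repetitions=3, seed=1)
        assert "baseline_error" in df.attrs
        assert "smallest_T_below_baseline" in df.attrs
        assert "smallest_T_within_one_std_of_best" in df.attrs

    def test_default_repetitions_is_ten(self):
        import inspect
        assert inspect.signature(convergence_curve).parameters["repetitions"].default == 10

    def test_empty_grid_rejected(self, quick_classifier):
        res, xte, yte = quick_classifier
        with pytest.raises(InvalidParameterError):
            convergence_curve(res.network, xte, yte, [], repetitions=3, seed=0)
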