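"""The small MLP engine: transfers, trainers, persistence, prediction."""

import numpy as np
import pytest

import weedvision as wv
from weedvision.mlp import MLPSpec, TrainedModel, fit_mlp


class TestSpecValidation:
    def test_zero_hidden_layers_rejected(self):
        with pytest.raises(ValueError):
            MLPSpec(hidden_sizes=(), transfers=())

    def test_three_hidden_layers_rejected(self):
        with pytest.raises(ValueError):
            MLPSpec(hidden_sizes=(5, 5, 5), transfers=("tansig",) * 3)

    def test_unknown_transfer_rejected(self):
        with pytest.raises(ValueError):
            MLPSpec(hidden_sizes=(5,), transfers=("relu",))

    def test_transfer_count_must_match(self):
        with pytest.raises(ValueError):
            MLPSpec(hidden_sizes=(5, 5), transfers=("tansig",))


class TestTraining:
    @pytest.mark.parametrize("training", ["levenberg_marquardt", "rprop",
                                          "gradient_descent"])
    def test_separable_data_learned(self, training, synthetic_table):
        spec = MLPSpec(hidden_sizes=(20,), transfers=("tansig",),
                       training=training, epochs=300, learning_rate=0.2)
        model = fit_mlp(synthetic_table.values, synthetic_table.labels, spec, seed=5)
        acc = np.mean(model.predict(synthetic_table.values) == synthetic_table.labels)
        assert acc == 1.0

    def test_two_hidden_layers_with_satlins(self, synthetic_table):
        spec = MLPSpec(hidden_sizes=(20, 12), transfers=("tansig", "satlins"),
                       training="rprop", epochs=200)
        model = fit_mlp(synthetic_table.values, synthetic_table.labels, spec, seed=3)
        acc = np.mean(model.predict(synthetic_table.values) == synthetic_table.labels)
        assert acc > 0.95

    def test_deterministic_given_seed(self, synthetic_table):
        spec = MLPSpec(hidden_sizes=(8,), transfers=("tansig",), epochs=30)
        a = fit_mlp(synthetic_table.values, synthetic_table.labels, spec, seed=9)
        b = fit_mlp(synthetic_table.values, synthetic_table.labels, spec, seed=9)
        for (Wa, ba), (Wb, bb) in zip(a.weights, b.weights):
            assert np.array_equal(Wa, Wb) and np.array_equal(ba, bb)

    def test_non_finite_features_rejected(self):
        X = np.array([[1.0, np.nan], [2.0, 3.0], [0.0, 1.0]])
        with pytest.raises(ValueError):
            fit_mlp(X, np.array([1, 2, 3]), MLPSpec(), seed=0)

    def test_train_mlp_stratified_split_recorded(self, synthetic_table):
        model = wv.train_mlp(synthetic_table, MLPSpec(epochs=20), seed=2)
        train_idx = model.meta["train_idx"]
        test_idx = model.meta["test_idx"]
        assert len(set(train_idx) & set(test_idx)) == 0
        assert len(train_idx) + len(test_idx) == synthetic_table.n_samples
        assert len(test_idx) == pytest.approx(0.3 * synthetic_table.n_samples, abs=1)


class TestPredict:
    def _constant_output_model(self, out_bias):
        spec = MLPSpec(hidden_sizes=(1,), transfers=("purelin",))
        weights = [[np.zeros((2, 1)), np.zeros(1)],
                   [np.zeros((1, 3)), np.asarray(out_bias, float)]]
        return TrainedModel(spec, weights, np.zeros(2), np.ones(2))

    def test_argmax_scores(self):
        model = self._constant_output_model([0.1, 0.8, 0.1])
        assert model.predict(np.zeros((1, 2)))[0] == 2

    def test_tie_breaks_to_lowest_class(self):
        model = self._constant_output_model([0.5, 0.5, 0.0])
        assert model.predict(np.zeros((1, 2)))[0] == 1

    def test_scores_sum_to_one(self, synthetic_table):
        model = wv.train_mlp(synthetic_table, MLPSpec(epochs=10), seed=0)
        s = model.scores(synthetic_table.values[:5])
        assert np.allclose(s.sum(axis=1), 1.0)

    def test_dimension_mismatch_rejected(self, synthetic_table):
        model = wv.train_mlp(synthetic_table, MLPSpec(epochs=5), seed=0)
        with pytest.raises(ValueError):
            model.predict(np.zeros((1, 99)))


def test_save_load_round_trip(tmp_path, synthetic_table):
    model = wv.train_mlp(synthetic_table, MLPSpec(epochs=30), seed=4)
    model.save(tmp_path / "model.json")
    loaded = TrainedModel.load(tmp_path / "model.json")
    X = synthetic_table.values
    assert np.array_equal(model.predict(X), loaded.predict(X))
    assert np.allclose(model.scores(X), loaded.scores(X))
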