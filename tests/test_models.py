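import numpy as np
import pytest

from sumosite import (
    EarlyStopping,
    ModelConfig,
    build_cnn,
    build_model,
    build_rscnn,
    build_tree_baseline,
    encode_windows,
    fit_tree,
    load_checkpoint,
    predict_scores,
    save_checkpoint,
    train_network,
)
from sumosite import nn


def small_cfg(algorithm, **kw):
    """Narrow nets (16 kernels) so unit tests stay fast; architecture logic
    is identical at any width."""
    return ModelConfig(algorithm=algorithm, kernels=16, **kw)


@pytest.fixture(scope="module")
def encoded_small():
    from sumosite import MotifModel, SyntheticDatasetSpec, generate_peptides

    ds = generate_peptides(SyntheticDatasetSpec(150, 150, MotifModel(L=15, seed=3)))
    X = encode_windows(ds.sequences, "zscale")
    return X.astype(np.float32), ds.labels


class TestArchitectures:
    def test_cnn_preserves_positions_before_flatten(self):
        model = build_cnn(small_cfg("cnn", n_conv_layers=1, seed=0), (39, 5))
        x = np.random.default_rng(0).standard_normal((2, 39, 5)).astype(np.float32)
        h = x
        for layer in model.estimator.layers:
            if isinstance(layer, nn.Flatten):
                assert h.shape == (2, 39, 16)
                break
            h = layer.forward(h, False, model.estimator.rng)

    @pytest.mark.parametrize("depth", [1, 2, 4, 6, 8])
    def test_depth_variants_build_and_score_in_unit_interval(self, depth):
        model = build_cnn(small_cfg("cnn", n_conv_layers=depth, seed=0), (15, 5))
        n_convs = sum(isinstance(l, nn.Conv1D) for l in model.estimator.layers)
        assert n_convs == depth
        x = np.random.default_rng(1).standard_normal((4, 15, 5)).astype(np.float32)
        model.fitted = True
        s = predict_scores(model, x)
        assert np.all((s > 0) & (s < 1))

    def test_rscnn_has_five_convolution_sublayers(self):
        model = build_rscnn(small_cfg("rscnn", seed=0), (39, 5))
        n_convs = 0
        for l in model.estimator.layers:
            if isinstance(l, nn.Conv1D):
                n_convs += 1
            elif isinstance(l, nn.ResidualBlock):
                n_convs += 2
        assert n_convs == 5

    def test_rscnn_forward_shape_reaches_flatten_at_full_length(self):
        model = build_rscnn(small_cfg("rscnn", seed=0), (39, 5))
        x = np.random.default_rng(0).standard_normal((2, 39, 5)).astype(np.float32)
        h = x
        for layer in model.estimator.layers:
            if isinstance(layer, nn.Flatten):
                assert h.shape == (2, 39, 16)
                break
            h = layer.forward(h, False, model.estimator.rng)

    def test_invalid_depth_rejected(self):
        with pytest.raises(ValueError):
            build_cnn(small_cfg("cnn", n_conv_layers=0), (39, 5))

    def test_wrong_algorithm_routed(self):
        with pytest.raises(ValueError):
            build_cnn(small_cfg("rscnn"), (39, 5))


class TestEarlyStopping:
    def test_peak_then_plateau_stops_after_patience(self):
        stopper = EarlyStopping(patience=50)
        accs = {e: (0.9 if e == 7 else 0.5) for e in range(1, 200)}
        stopped_at = None
        for epoch in range(1, 200):
            if stopper.update(epoch, accs[epoch]):
                stopped_at = epoch
                break
        assert stopped_at == 57
        assert stopper.best_epoch == 7

    def test_single_epoch_budget(self, encoded_small):
        X, y = encoded_small
        model = build_cnn(small_cfg("cnn", n_conv_layers=1, seed=0), X.shape[1:])
        train_network(model, X[:200], y[:200], X[200:], y[200:],
                      max_epochs=1, batch_size=64)
        assert [r["epoch"] for r in model.training_log] == [1]

    def test_best_state_is_restored(self, encoded_small):
        X, y = encoded_small
        model = build_cnn(small_cfg("cnn", n_conv_layers=1, seed=0), X.shape[1:])
        train_network(model, X[:200], y[:200], X[200:], y[200:],
                      max_epochs=4, patience=4, batch_size=64)
        best = max(r["val_acc"] for r in model.training_log)
        scores = predict_scores(model, X[200:])
        assert np.mean((scores > 0.5) == y[200:]) == pytest.approx(best)


class TestTrainingContract:
    def test_shape_mismatch_detected_before_training(self, encoded_small):
        X, y = encoded_small
        model = build_cnn(small_cfg("cnn", seed=0), X.shape[1:])
        with pytest.raises(ValueError, match="shape mismatch"):
            train_network(model, X[:100], y[:100], X[100:, :10], y[100:])

    def test_unfitted_model_refuses_to_predict(self, encoded_small):
        X, _ = encoded_small
        model = build_cnn(small_cfg("cnn", seed=0), X.shape[1:])
        with pytest.raises(RuntimeError, match="not fitted"):
            predict_scores(model, X)

    def test_seeded_training_is_reproducible(self, encoded_small):
        X, y = encoded_small
        scores = []
        for _ in range(2):
            m = build_rscnn(small_cfg("rscnn", seed=9), X.shape[1:])
            train_network(m, X[:200], y[:200], X[200:], y[200:],
                          max_epochs=2, batch_size=64)
            scores.append(predict_scores(m, X[200:]))
        np.testing.assert_array_equal(scores[0], scores[1])

    def test_batch_invariance_of_prediction(self, encoded_small):
        X, y = encoded_small
        m = build_cnn(small_cfg("cnn", n_conv_layers=1, seed=2), X.shape[1:])
        train_network(m, X[:200], y[:200], X[200:], y[200:],
                      max_epochs=1, batch_size=64)
        whole = predict_scores(m, X[:32])
        single = np.concatenate([predict_scores(m, X[i:i+1]) for i in range(32)])
        np.testing.assert_allclose(whole, single, atol=1e-6)

    def test_training_log_csv(self, encoded_small, tmp_path):
        X, y = encoded_small
        m = build_cnn(small_cfg("cnn", n_conv_layers=1, seed=0), X.shape[1:])
        train_network(m, X[:150], y[:150], X[150:], y[150:],
                      max_epochs=2, batch_size=64)
        f = tmp_path / "log.csv"
        m.training_log_csv(f)
        lines = f.read_text().splitlines()
        assert lines[0] == "epoch,train_loss,train_acc,val_loss,val_acc"
        assert len(lines) == 3


class TestTreeBaselines:
    def test_rf_has_140_trees(self):
        model = build_tree_baseline(ModelConfig(algorithm="rf"), (39, 5))
        assert model.estimator.n_estimators == 140

    def test_separable_toy_data_fits_perfectly(self):
        rng = np.random.default_rng(0)
        X = np.concatenate([rng.normal(-3, 0.3, (50, 1, 2)),
                            rng.normal(3, 0.3, (50, 1, 2))])
        y = np.array([0] * 50 + [1] * 50)
        for alg in ("rf", "lgbm"):
            m = fit_tree(build_tree_baseline(ModelConfig(algorithm=alg, seed=0),
                                             (1, 2)), X, y)
            acc = np.mean((predict_scores(m, X) > 0.5) == y)
            assert acc == 1.0

    def test_deterministic_given_seed(self, encoded_small):
        X, y = encoded_small
        runs = []
        for _ in range(2):
            m = fit_tree(build_tree_baseline(ModelConfig(algorithm="rf", seed=5),
                                             X.shape[1:]), X, y)
            runs.append(predict_scores(m, X[:20]))
        np.testing.assert_array_equal(runs[0], runs[1])


def test_checkpoint_roundtrip(encoded_small, tmp_path):
    X, y = encoded_small
    m = build_rscnn(small_cfg("rscnn", seed=4), X.shape[1:])
    train_network(m, X[:200], y[:200], X[200:], y[200:], max_epochs=1,
                  batch_size=64)
    before = predict_scores(m, X[:25])
    save_checkpoint(m, tmp_path / "ckpt", channel_order="zscale")
    m2 = load_checkpoint(tmp_path / "ckpt")
    np.testing.assert_array_equal(predict_scores(m2, X[:25]), before)
    assert m2.config.algorithm == "rscnn"
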