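"""Detector construction, training contracts, gradient correctness."""
import numpy as np
import pytest

from gutsound import (
    ConfigError,
    DetectorConfig,
    ValidationError,
    binarize,
    build_detector,
    load_detector,
    predict_frames,
    save_detector,
    train,
)
from gutsound import nn as _nn_module  # noqa: F401  (re-exported below)
from gutsound.nn import softmax_cross_entropy


def toy_dataset(n=256, seed=0):
    """Linearly separable patches: energy in band 0 vs band 2."""
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 0.1, size=(n, 3, 11))
    y = rng.integers(0, 2, size=n)
    x[y == 1, 0, :] += 2.0
    x[y == 0, 2, :] += 2.0
    return x, y


class TestConfig:
    def test_channel_count_must_match_blocks(self):
        with pytest.raises(ConfigError):
            DetectorConfig(channels=(8, 16))

    def test_pooling_below_one_rejected(self):
        with pytest.raises(ConfigError):
            build_detector(DetectorConfig(input_width=5))  # 5 -> 2 -> 1 -> 0

    def test_time_width_shrinks_11_5_2_1(self):
        assert DetectorConfig().pooled_width() == 1

    def test_cnn_parameter_count_closed_form(self):
        cfg = DetectorConfig()
        det = build_detector(cfg)
        expected = 0
        in_ch = 1
        for b in range(cfg.n_blocks):
            out = cfg.channels[b]
            for _ in range(cfg.convs_per_block):
                expected += out * in_ch * 9 + out  # conv W + b
                expected += 2 * out  # batch-norm gamma + beta
                in_ch = out
        expected += (cfg.channels[-1] * 3 * 1) * 2 + 2  # FC head
        assert det.n_params == expected

    def test_lstm_parameter_count_closed_form(self):
        cfg = DetectorConfig(arch="lstm")
        det = build_detector(cfg)
        h = cfg.lstm_hidden
        expected = (3 + h) * 4 * h + 4 * h  # layer 0
        expected += (h + h) * 4 * h + 4 * h  # layer 1
        expected += h * 2 + 2  # FC head
        assert det.n_params == expected


class TestForward:
    @pytest.mark.parametrize("arch", ["cnn", "lstm"])
    def test_probabilities_sum_to_one(self, arch):
        det = build_detector(DetectorConfig(arch=arch, seed=0))
        x = np.random.default_rng(1).normal(size=(7, 3, 11))
        from gutsound.nn import softmax

        probs = softmax(det.forward(x))
        assert probs.shape == (7, 2)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(probs >= 0)

    def test_shape_mismatch_rejected(self):
        det = build_detector(DetectorConfig(seed=0))
        with pytest.raises(ValidationError):
            predict_frames(det, np.zeros((5, 4, 11)))


class TestTraining:
    def test_separable_toy_reaches_perfect_accuracy(self):
        x, y = toy_dataset()
        det = build_detector(DetectorConfig(seed=0, dropout_rate=0.0))
        train(det, x, y, iterations=200)
        acc = np.mean(binarize(predict_frames(det, x)) == y)
        assert acc == 1.0

    def test_same_seed_same_loss_trajectory(self):
        x, y = toy_dataset()
        losses = []
        for _ in range(2):
            det = build_detector(DetectorConfig(seed=3))
            train(det, x, y, iterations=30)
            losses.append(det.training_log)
        assert losses[0] == losses[1]

    def test_zero_iterations_is_noop(self):
        x, y = toy_dataset()
        det = build_detector(DetectorConfig(seed=1))
        before = [p.copy() for layer in det.net.layers for p in layer.params.values()]
        train(det, x, y, iterations=0)
        after = [p for layer in det.net.layers for p in layer.params.values()]
        for b, a in zip(before, after):
            assert np.array_equal(b, a)

    def test_zero_learning_rate_freezes_parameters(self):
        x, y = toy_dataset()
        det = build_detector(DetectorConfig(seed=1, learning_rate=0.0))
        before = [p.copy() for layer in det.net.layers for p in layer.params.values()]
        train(det, x, y, iterations=10)
        for b, a in zip(before, (p for l in det.net.layers for p in l.params.values())):
            assert np.allclose(b, a)

    def test_training_loss_always_finite(self):
        x, y = toy_dataset()
        det = build_detector(DetectorConfig(seed=2))
        train(det, x, y, iterations=100)
        assert np.all(np.isfinite(det.training_log))

    def test_single_class_dataset_rejected(self):
        x, _ = toy_dataset()
        with pytest.raises(ValidationError, match="single class"):
            train(build_detector(DetectorConfig(seed=0)), x, np.zeros(len(x)))

    @pytest.mark.parametrize("arch", ["cnn", "lstm"])
    def test_gradients_match_finite_differences(self, arch):
        # numerical check of the full backward pass through a tiny batch
        x, y = toy_dataset(n=8, seed=5)
        det = build_detector(DetectorConfig(arch=arch, seed=4, dropout_rate=0.0))

        def loss_at():
            logits = det.net.forward(x, train=False)
            return softmax_cross_entropy(logits, y)[0]

        logits = det.net.forward(x, train=False)
        _, dlogits = softmax_cross_entropy(logits, y)
        det.net.backward(dlogits)
        rng = np.random.default_rng(0)
        eps = 1e-6
        for layer in det.net.layers:
            for name, p in layer.params.items():
                flat_idx = rng.integers(0, p.size, size=min(3, p.size))
                for idx in flat_idx:
                    orig = p.flat[idx]
                    p.flat[idx] = orig + eps
                    up = loss_at()
                    p.flat[idx] = orig - eps
                    down = loss_at()
                    p.flat[idx] = orig
                    numeric = (up - down) / (2 * eps)
                    analytic = layer.grads[name].flat[idx]
                    assert numeric == pytest.approx(analytic, rel=1e-3, abs=1e-6), (
                        f"{type(layer).__name__}.{name}[{idx}]"
                    )


class TestPredict:
    def test_constant_patches_are_never_bowel_sounds(self):
        # pure silence standardizes to all-zero patches; they must decode
        # to p = 0 regardless of where the classifier's boundary sits
        x, y = toy_dataset()
        det = build_detector(DetectorConfig(seed=0))
        train(det, x, y, iterations=50)
        silent = np.zeros((10, 3, 11))
        assert np.all(predict_frames(det, silent) == 0.0)

    def test_binarize_threshold_convention(self):
        assert binarize(np.array([0.49, 0.50, 0.51]), 0.5).tolist() == [0, 1, 1]

    def test_binarize_extreme_threshold(self):
        probs = np.array([0.2, 0.999, 1.0])
        # threshold just under 1 keeps only near-certain frames
        assert binarize(probs, 0.9995).tolist() == [0, 0, 1]

    def test_checkpoint_round_trip(self, tmp_path):
        x, y = toy_dataset()
        det = build_detector(DetectorConfig(seed=0))
        train(det, x, y, iterations=50)
        path = tmp_path / "model.npz"
        save_detector(det, path)
        clone = load_detector(path)
        assert np.allclose(predict_frames(det, x), predict_frames(clone, x))
        assert clone.config == det.config
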