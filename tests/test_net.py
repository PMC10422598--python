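"""Improved-AlexNet classifier: architecture, gradients, training metrics."""

import numpy as np
import pytest

import soyemerge._kernels as kernels
from soyemerge.net import (
    EvalResult,
    Model,
    NetConfig,
    TrainConfig,
    TrainingHistory,
    _MaxPool,
    _cross_entropy,
    average_metrics,
    build_model,
    classify_crops,
    evaluate,
    train,
)

TINY = NetConfig(input_shape=(17, 17, 2), conv_kernels=(3, 3, 3, 3, 3),
                 conv_channels=(2, 3, 3, 3, 2), fc_sizes=(8, 6),
                 dropout=0.0, lrn=True)

# 63 -> 31 -> 15 -> 7 through the three overlapping pools: a fast smoke shape
SMALL = NetConfig(input_shape=(63, 63, 3), conv_kernels=(7, 5, 3, 3, 3),
                  conv_channels=(2, 4, 6, 6, 4), fc_sizes=(32, 16), dropout=0.3)


def _small_crops(rng, n_per_class, classes=(0, 1, 2), size=63):
    bases = np.array([[200, 60, 60], [60, 200, 60], [60, 60, 200]])
    xs, ys = [], []
    for c in classes:
        block = bases[c][None, None, None, :] + rng.normal(0, 20, (n_per_class, size, size, 3))
        xs.append(np.clip(block, 0, 255).astype(np.uint8))
        ys.append(np.full(n_per_class, c, dtype=np.int64))
    return np.concatenate(xs), np.concatenate(ys)


class TestArchitecture:
    def test_layer_census_default_config(self):
        model = build_model(NetConfig.desk_scale())
        desc = model.describe()
        assert desc["conv_layers"] == 5
        assert desc["pool_layers"] == 3
        assert desc["fc_layers"] == 3

    def test_overlapping_pool_size_arithmetic(self):
        assert _MaxPool.out_size(15, 3, 2) == 7
        assert _MaxPool.out_size(255, 3, 2) == 127

    def test_spatial_chain_of_default_input(self):
        model = build_model(NetConfig.desk_scale())
        assert model.describe()["final_spatial"] == (31, 31)

    def test_parameter_count_hand_summed(self):
        cfg = NetConfig(input_shape=(31, 31, 1), conv_kernels=(3, 3, 3, 3, 3),
                        conv_channels=(1, 1, 1, 1, 1), fc_sizes=(4, 2),
                        dropout=0.0, lrn=False)
        model = build_model(cfg)
        # convs: (3*3*1*1 + 1) * 5 ; spatial 31 -> 15 -> 7 -> 3 ; flatten 9
        conv = (9 + 1) * 5
        fc = (9 * 4 + 4) + (4 * 2 + 2) + (2 * 3 + 3)
        assert model.count_params() == conv + fc

    def test_spatial_underflow_raises(self):
        with pytest.raises(ValueError, match="underflow"):
            build_model(NetConfig(input_shape=(9, 9, 3)))

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            NetConfig(conv_kernels=(3, 3)).validate()
        with pytest.raises(ValueError):
            NetConfig(dropout=1.0).validate()


class TestGradients:
    def test_backprop_matches_numeric_gradients(self):
        model = build_model(TINY, seed=1)
        rng = np.random.default_rng(0)
        x = rng.standard_normal((3, 17, 17, 2)).astype(np.float32)
        y = np.array([0, 1, 2])

        def loss_at():
            logits = model.forward(x.copy(), train=False)
            return _cross_entropy(logits, y)[0]

        loss, dlogits = _cross_entropy(model.forward(x.copy(), train=False), y)
        model.backward(dlogits)
        grads = [g.copy() for g in model.grads]
        eps = 1e-3
        idx_rng = np.random.default_rng(5)
        for pi, p in enumerate(model.params):
            flat, g = p.ravel(), grads[pi].ravel()
            for _ in range(3):
                j = int(idx_rng.integers(flat.size))
                old = flat[j]
                flat[j] = old + eps
                lp = loss_at()
                flat[j] = old - eps
                lm = loss_at()
                flat[j] = old
                num = (lp - lm) / (2 * eps)
                assert abs(num - g[j]) < 1e-3 * max(1.0, abs(num), abs(g[j]))

    def test_numba_and_numpy_paths_agree(self):
        if not kernels.HAS_NUMBA:
            # only one path exists; nothing to compare
            return
        model = build_model(TINY, seed=2)
        rng = np.random.default_rng(1)
        x = rng.standard_normal((2, 17, 17, 2)).astype(np.float32)
        y = np.array([0, 2])
        out_nb = model.forward(x.copy(), train=False).copy()
        _, dl = _cross_entropy(out_nb, y)
        model.backward(dl)
        g_nb = [g.copy() for g in model.grads]
        kernels.HAS_NUMBA = False
        try:
            out_np = model.forward(x.copy(), train=False).copy()
            model.backward(dl)
            g_np = [g.copy() for g in model.grads]
        finally:
            kernels.HAS_NUMBA = True
        assert np.allclose(out_nb, out_np, atol=1e-5)
        for a, b in zip(g_nb, g_np):
            assert np.allclose(a, b, atol=1e-5)


class TestTraining:
    def test_smoke_run_contract(self):
        rng = np.random.default_rng(3)
        Xtr, ytr = _small_crops(rng, 12)
        Xte, yte = _small_crops(rng, 4)
        model = build_model(SMALL, seed=3)
        history = train(model, (Xtr, ytr), (Xte, yte),
                        TrainConfig(epochs=2, seed=3, learning_rate=1e-3))
        assert history.e == 2
        assert all(np.isfinite(history.loss))
        assert all(0.0 <= a <= 1.0 for a in history.accuracy)

    def test_separable_two_class_reaches_perfect_accuracy(self):
        rng = np.random.default_rng(4)
        Xtr, ytr = _small_crops(rng, 24, classes=(0, 1))
        Xte, yte = _small_crops(rng, 8, classes=(0, 1))
        model = build_model(SMALL, seed=4)
        history = train(model, (Xtr, ytr), (Xte, yte),
                        TrainConfig(epochs=12, seed=4, learning_rate=1e-3))
        assert max(history.accuracy) == 1.0

    def test_fixed_seed_reproduces_first_epoch_loss(self):
        rng = np.random.default_rng(5)
        Xtr, ytr = _small_crops(rng, 8)
        Xte, yte = _small_crops(rng, 3)
        h1 = train(build_model(SMALL, seed=5), (Xtr, ytr), (Xte, yte),
                   TrainConfig(epochs=1, seed=5))
        h2 = train(build_model(SMALL, seed=5), (Xtr, ytr), (Xte, yte),
                   TrainConfig(epochs=1, seed=5))
        assert h1.loss[0] == h2.loss[0]
        assert h1.train_loss[0] == h2.train_loss[0]

    def test_empty_split_rejected(self):
        model = build_model(SMALL, seed=0)
        X = np.zeros((0, 63, 63, 3), np.uint8)
        with pytest.raises(ValueError):
            train(model, (X, np.zeros(0, np.int64)), (X, np.zeros(0, np.int64)))


class TestMetrics:
    def test_average_metrics_hand_values(self):
        h = TrainingHistory(loss=[1.0, 0.5], accuracy=[0.9, 1.0])
        al, aa = average_metrics(h)
        assert al == pytest.approx(0.75)
        assert aa == pytest.approx(95.0)

    def test_single_epoch_identity(self):
        h = TrainingHistory(loss=[0.42], accuracy=[0.81])
        al, aa = average_metrics(h)
        assert al == pytest.approx(0.42) and aa == pytest.approx(81.0)

    def test_matches_independent_recomputation(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            e = int(rng.integers(1, 60))
            losses = rng.uniform(0, 3, e).tolist()
            accs = rng.uniform(0, 1, e).tolist()
            h = TrainingHistory(loss=losses, accuracy=accs)
            al, aa = average_metrics(h)
            assert al == pytest.approx(sum(losses) / e, abs=1e-12)
            assert aa == pytest.approx(100.0 * sum(accs) / e, abs=1e-12)
            assert h.e_L == pytest.approx(sum(losses), abs=1e-9)

    def test_empty_history_rejected(self):
        with pytest.raises(ValueError):
            average_metrics(TrainingHistory())


@pytest.fixture(scope="module")
def trained():
    rng = np.random.default_rng(7)
    Xtr, ytr = _small_crops(rng, 16)
    Xte, yte = _small_crops(rng, 6)
    model = build_model(SMALL, seed=7)
    train(model, (Xtr, ytr), (Xte, yte),
          TrainConfig(epochs=8, seed=7, learning_rate=1e-3))
    return model, Xte, yte


class TestEvaluate:

    def test_accuracy_is_correct_over_total(self, trained):
        model, Xte, yte = trained
        res = evaluate(model, Xte, yte)
        assert res.accuracy == res.n_correct / res.n_total
        assert res.n_total == len(yte)

    def test_accuracy_equals_confusion_trace_ratio(self, trained):
        model, Xte, yte = trained
        res = evaluate(model, Xte, yte)
        assert res.accuracy == pytest.approx(
            np.trace(res.confusion) / res.confusion.sum())
        assert res.confusion.sum(axis=1).tolist() == [6, 6, 6]

    def test_eval_result_arithmetic(self):
        # A = N_C / N_T directly
        res = EvalResult(accuracy=0.99, n_correct=99, n_total=100,
                         per_class_accuracy=(1, 1, 0.97), confusion=np.eye(3))
        assert res.n_correct / res.n_total == pytest.approx(0.99)


class TestClassifyCrops:
    def test_contract_and_determinism(self):
        rng = np.random.default_rng(8)
        model = build_model(NetConfig(conv_channels=(2, 2, 2, 2, 2),
                                      fc_sizes=(8, 4)), seed=8)
        crops = rng.integers(0, 256, (3, 255, 255, 3)).astype(np.uint8)
        dup = np.concatenate([crops, crops[:1]])
        labels = classify_crops(model, dup)
        assert labels.shape == (4,)
        assert set(labels.tolist()) <= {0, 1, 2}
        assert labels[0] == labels[3]  # duplicated crop, identical label

    def test_softmax_normalised(self):
        rng = np.random.default_rng(9)
        model = build_model(SMALL, seed=9)
        x = rng.integers(0, 256, (4, 63, 63, 3)).astype(np.uint8)
        probs = model.predict_proba(x)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-5)

    def test_wrong_shape_rejected(self):
        model = build_model(SMALL, seed=10)
        with pytest.raises(ValueError):
            classify_crops(model, [np.zeros((64, 64, 3), np.uint8)])


class TestPersistence:
    def test_save_load_roundtrip(self, tmp_path):
        rng = np.random.default_rng(11)
        model = build_model(SMALL, seed=11)
        x = rng.integers(0, 256, (2, 63, 63, 3)).astype(np.uint8)
        before = model.predict_proba(x)
        path = tmp_path / "weights.npz"
        model.save(path)
        loaded = Model.load(path)
        after = loaded.predict_proba(x)
        assert np.allclose(before, after, atol=1e-6)
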