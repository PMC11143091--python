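"""Architecture conformance, forward/backward correctness, training contracts."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from p300decode.nn import EEGNetConfig, TrainConfig, build_model
from p300decode.nn.ops import focal_loss_grad_logits
from p300decode.nn.train import confusion_metrics, evaluate_loso, train, train_on
from .conftest import make_epochset

TABLE_SHAPES = [
    ("input", (8, 201)),
    ("reshape", (1, 8, 201)),
    ("conv_temporal", (8, 1, 201)),
    ("batchnorm1", (8, 1, 201)),
    ("depthwise", (16, 1, 201)),
    ("batchnorm2", (16, 1, 201)),
    ("elu1", (16, 1, 201)),
    ("avgpool1", (16, 1, 50)),
    ("dropout1", (16, 1, 50)),
    ("separable", (16, 1, 50)),
    ("batchnorm3", (16, 1, 50)),
    ("elu2", (16, 1, 50)),
    ("avgpool2", (16, 1, 6)),
    ("dropout2", (16, 1, 6)),
    ("flatten", (96,)),
    ("dense", (2,)),
]


class TestArchitecture:
    def test_layer_shapes_match_table(self):
        assert build_model().layer_shapes() == TABLE_SHAPES

    def test_flatten_96(self):
        assert EEGNetConfig().flatten_length == 96

    def test_pool_lengths(self):
        cfg = EEGNetConfig()
        assert cfg.pool1_length == 50
        assert cfg.pool2_length == 6

    def test_flatten_for_100_samples(self):
        cfg = EEGNetConfig(n_samples=100)
        assert cfg.flatten_length == 16 * ((100 // 4) // 8) == 48

    def test_zero_length_pooling_rejected(self):
        with pytest.raises(ValueError):
            EEGNetConfig(n_samples=20)

    def test_true_tensor_shapes(self):
        shapes = EEGNetConfig().tensor_shapes()
        assert shapes["conv_temporal"] == (8, 8, 201)
        assert shapes["avgpool1"] == (16, 50)
        assert shapes["flatten"] == (96,)

    def test_forward_shapes_agree_with_report(self):
        m = build_model(seed=0)
        x = np.random.default_rng(0).standard_normal((3, 8, 201))
        logits, caches = m.forward(x)
        assert logits.shape == (3, 2)


class TestForward:
    def test_probabilities_sum_to_one(self):
        m = build_model(seed=1)
        x = np.random.default_rng(1).standard_normal((16, 8, 201))
        p = m.predict_proba(x)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert ((p >= 0) & (p <= 1)).all()

    def test_eval_forward_deterministic(self):
        m = build_model(seed=2)
        x = np.random.default_rng(2).standard_normal((4, 8, 201))
        np.testing.assert_array_equal(m.predict_proba(x), m.predict_proba(x))

    def test_save_load_roundtrip(self, tmp_path):
        m = build_model(seed=3)
        x = np.random.default_rng(3).standard_normal((4, 8, 201))
        p1 = m.predict_proba(x)
        m.save(tmp_path / "model.npz")
        from p300decode.nn.model import EEGNet

        m2 = EEGNet.load(tmp_path / "model.npz")
        np.testing.assert_array_equal(p1, m2.predict_proba(x))


class TestInputGradient:
    """The finite-difference oracle the saliency module depends on."""

    def test_matches_finite_differences(self):
        rng = np.random.default_rng(7)
        m = build_model(seed=11)
        for bn in m.bn_state.values():  # nontrivial eval-mode statistics
            bn["mean"] = rng.normal(0, 0.1, bn["mean"].shape)
            bn["var"] = 1 + rng.uniform(0, 0.5, bn["var"].shape)
        x = rng.standard_normal((2, 8, 201))
        g = m.input_gradient(x, 1)
        eps = 1e-5
        for _ in range(20):
            n, c, t = rng.integers(2), rng.integers(8), rng.integers(201)
            xp, xm = x.copy(), x.copy()
            xp[n, c, t] += eps
            xm[n, c, t] -= eps
            fd = (m.class_score(xp, 1)[n] - m.class_score(xm, 1)[n]) / (2 * eps)
            assert g[n, c, t] == pytest.approx(fd, rel=1e-3, abs=1e-10)

    def test_parameter_gradients_match_finite_differences(self):
        rng = np.random.default_rng(8)
        m = build_model(seed=12)
        x = rng.standard_normal((3, 8, 201))
        y = np.array([1, 0, 0])

        def loss():
            logits, _ = m.forward(x, training=False)
            return focal_loss_grad_logits(logits, y, 2.0)[0]

        logits, caches = m.forward(x, training=False)
        _, dl = focal_loss_grad_logits(logits, y, 2.0)
        grads, _ = m.backward(dl, caches)
        eps = 1e-5
        for k, g in grads.items():
            w = m.params[k]
            idx = tuple(rng.integers(s) for s in w.shape)
            saved = w[idx]
            w[idx] = saved + eps
            lp = loss()
            w[idx] = saved - eps
            lm = loss()
            w[idx] = saved
            fd = (lp - lm) / (2 * eps)
            assert g[idx] == pytest.approx(fd, rel=1e-4, abs=1e-9), k

    def test_class_index_out_of_range(self):
        m = build_model()
        with pytest.raises(IndexError):
            m.input_gradient(np.zeros((8, 201)), 5)


class TestTraining:
    def test_zero_epochs_returns_initial_model(self, separable_epochs):
        m = build_model(seed=0)
        before = {k: v.copy() for k, v in m.params.items()}
        tcfg = TrainConfig(max_epochs=0)
        m2, history = train(m, separable_epochs, None, tcfg)
        assert history.empty
        for k in before:
            np.testing.assert_array_equal(before[k], m2.params[k])

    def test_separable_set_reaches_100(self, separable_epochs):
        tcfg = TrainConfig(
            learning_rate=1e-3, max_epochs=50, patience=50, batch_size=32,
            seed=0, dtype="float32",
        )
        model, history = train_on(separable_epochs, EEGNetConfig(dropout_rate=0.25), tcfg)
        assert history["val_accuracy"].max() == pytest.approx(100.0)

    def test_single_class_rejected(self, layout):
        data = np.zeros((8, 8, 201))
        es = make_epochset(data, np.zeros(8, int), layout)
        with pytest.raises(ValueError):
            train(build_model(), es, None, TrainConfig(max_epochs=1))

    def test_determinism(self, separable_epochs):
        tcfg = TrainConfig(learning_rate=1e-3, max_epochs=3, batch_size=32, seed=5)
        m1, h1 = train_on(separable_epochs, EEGNetConfig(), tcfg)
        m2, h2 = train_on(separable_epochs, EEGNetConfig(), tcfg)
        for k in m1.params:
            np.testing.assert_array_equal(m1.params[k], m2.params[k])
        pd.testing.assert_frame_equal(h1, h2)

    def test_focal_gamma_improves_sensitivity_on_imbalanced_toy(self, layout):
        """gamma=2 should not hurt sensitivity vs gamma=0 on a 1:7 toy set."""
        rng = np.random.default_rng(9)
        from p300decode.epochs import epoch_times

        times = epoch_times()
        n = 256
        labels = (np.arange(n) % 8 == 0).astype(int)
        bump = 2.0 * np.exp(-0.5 * ((times - 400.0) / 50.0) ** 2)
        topo = layout.gaussian_topography("Pz", spread=0.3)
        data = rng.normal(0, 2.0, size=(n, 8, len(times)))
        data[labels == 1] += topo[:, None] * bump[None, :]
        es = make_epochset(data, labels, layout)
        sens = {}
        for gamma in (0.0, 2.0):
            tcfg = TrainConfig(
                learning_rate=1e-3, max_epochs=15, patience=15, batch_size=64,
                focal_gamma=gamma, seed=3, dtype="float32",
            )
            model, _ = train_on(es, EEGNetConfig(dropout_rate=0.25), tcfg)
            m = confusion_metrics(model.predict(es.data), es.labels)
            sens[gamma] = m.sensitivity
        assert sens[2.0] >= sens[0.0]


class TestConfusionMetrics:
    def test_all_correct(self):
        m = confusion_metrics(np.array([1, 0, 1, 0]), np.array([1, 0, 1, 0]))
        assert (m.accuracy, m.sensitivity, m.specificity) == (100.0, 100.0, 100.0)

    def test_derived_counts(self):
        preds = np.concatenate([np.ones(7), np.zeros(3), np.zeros(80), np.ones(10)]).astype(int)
        labels = np.concatenate([np.ones(10), np.zeros(90)]).astype(int)
        m = confusion_metrics(preds, labels)
        assert (m.tp, m.fn, m.tn, m.fp) == (7, 3, 80, 10)
        assert m.sensitivity == pytest.approx(70.0)
        assert m.specificity == pytest.approx(88.9, abs=0.05)
        assert m.accuracy == pytest.approx(87.0)

    def test_degenerate_all_negative(self):
        m = confusion_metrics(np.zeros(5, int), np.zeros(5, int))
        assert m.specificity == 100.0
        assert np.isnan(m.sensitivity)
        assert any("sensitivity undefined" in f for f in m.flags)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(np.array([]), np.array([]))

    def test_internal_consistency_accuracy_from_counts(self):
        rng = np.random.default_rng(1)
        preds = rng.integers(0, 2, 200)
        labels = rng.integers(0, 2, 200)
        m = confusion_metrics(preds, labels)
        recomputed = 100.0 * (m.tp + m.tn) / m.n
        assert abs(recomputed - m.accuracy) < 0.1


@pytest.fixture(scope="module")
def twin_dataset(layout):
    """Two subjects with identical noise-free separable data."""
    from p300decode.epochs import EpochSet, epoch_times

    times = epoch_times()
    n = 64
    labels = (np.arange(n) % 8 == 0).astype(int)
    bump = 5.0 * np.exp(-0.5 * ((times - 400.0) / 50.0) ** 2)
    topo = layout.gaussian_topography("Pz", spread=0.3)
    rng = np.random.default_rng(3)
    data = rng.normal(0, 0.2, size=(n, 8, len(times)))
    data[labels == 1] += topo[:, None] * bump[None, :]
    parts = []
    for subj in (1, 2):
        parts.append(make_epochset(data.copy(), labels, layout, subject=subj))
    return EpochSet.concatenate(parts)


class TestLoso:
    def test_identical_subjects_both_100(self, twin_dataset):
        tcfg = TrainConfig(
            learning_rate=1e-3, max_epochs=30, patience=30, batch_size=32,
            seed=0, dtype="float32",
        )
        metrics, models = evaluate_loso(twin_dataset, EEGNetConfig(dropout_rate=0.25), tcfg)
        assert len(models) == 2  # exactly k train/test cycles
        pooled = metrics[metrics["scenario"] == "all"]
        assert (pooled["accuracy"] == 100.0).all()

    def test_single_subject_rejected(self, separable_epochs):
        with pytest.raises(ValueError):
            evaluate_loso(separable_epochs, EEGNetConfig(), TrainConfig(max_epochs=1))
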