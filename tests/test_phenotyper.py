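"""Preprocessing, augmentation, leaf detection, builders, training, metrics."""

from __future__ import annotations

import numpy as np
import pytest

from pestgs.nn import Dense, ScaledSigmoid, Sequential
from pestgs.phenotyper import (
    BinaryNetConfig,
    LeafNotFoundError,
    PdsNetConfig,
    augment,
    build_binary_network,
    build_pds_network,
    classification_metrics,
    crossvalidate,
    detect_leaf_bbox,
    preprocess_image,
    regression_metrics,
    sample_augmentation_params,
    train_with_early_stopping,
)
from pestgs.simdata import generate_leaf_image


class TestPreprocess:
    def test_resize_and_normalise(self):
        raw = np.random.default_rng(0).integers(0, 256, (500, 400, 3), dtype=np.uint8)
        out = preprocess_image(raw, input_size=224)
        assert out.shape == (224, 224, 3)
        assert out.max() <= 1.0 and out.min() >= 0.0

    def test_idempotent_on_conforming_input(self):
        x = np.zeros((224, 224, 3), dtype=np.float32)
        np.testing.assert_array_equal(preprocess_image(x), x)

    def test_uint8_scaling_by_255(self):
        x = np.full((32, 32, 3), 128, dtype=np.uint8)
        out = preprocess_image(x, input_size=32)
        assert np.allclose(out, 128 / 255, atol=1e-6)

    def test_non_rgb_rejected(self):
        with pytest.raises(ValueError):
            preprocess_image(np.zeros((10, 10), dtype=np.uint8))


class TestAugment:
    def test_seed_determinism(self):
        img = generate_leaf_image(0.3, 64, 1).pixels.astype(np.float32)
        a = augment(img, seed=5)
        b = augment(img, seed=5)
        np.testing.assert_array_equal(a, b)
        assert a.shape == img.shape and a.min() >= 0 and a.max() <= 1

    def test_flip_only_on_symmetric_image(self):
        img = np.random.default_rng(0).random((16, 16, 3)).astype(np.float32)
        sym = np.clip((img + img[:, ::-1, :]) / 2, 0, 1)
        for seed in range(10):
            out = augment(sym, seed=seed, rotation_deg=0, shift_frac=0, zoom_range=0)
            np.testing.assert_allclose(out, sym, atol=1e-6)

    def test_sampled_angles_stay_in_bounds(self):
        angles = [sample_augmentation_params(s)["angle"] for s in range(1000)]
        assert min(angles) >= -45.0 and max(angles) <= 45.0
        zooms = [sample_augmentation_params(s)["zoom"] for s in range(1000)]
        assert min(zooms) >= 0.5 and max(zooms) <= 1.5


class TestLeafDetection:
    def test_box_covers_leaf_mask(self):
        leaf = generate_leaf_image(0.2, 96, 3)
        r0, c0, r1, c1 = detect_leaf_bbox(leaf.pixels)
        inside = leaf.leaf_mask[r0:r1, c0:c1].sum()
        assert inside / leaf.leaf_mask.sum() >= 0.99

    def test_background_only_not_found(self):
        img = np.zeros((32, 32, 3))
        img[:, :, 0] = 0.5  # red-dominant everywhere
        with pytest.raises(LeafNotFoundError):
            detect_leaf_bbox(img)

    def test_full_frame_leaf(self):
        img = np.zeros((20, 20, 3))
        img[:, :, 1] = 1.0  # green everywhere
        assert detect_leaf_bbox(img) == (0, 0, 20, 20)


class TestBuilders:
    def test_pds_output_bounds_and_determinism(self):
        cfg = PdsNetConfig.tiny()
        a = build_pds_network(cfg, seed=3)
        b = build_pds_network(cfg, seed=3)
        assert a.n_params() == b.n_params()
        x = np.random.default_rng(0).random((2, 64, 64, 3)).astype(np.float32)
        out = a.forward(x)
        np.testing.assert_array_equal(out, b.forward(x))
        assert np.all(out >= 0) and np.all(out <= 5)

    def test_pds_config_invariants(self):
        with pytest.raises(ValueError):
            PdsNetConfig(residual_block_filters=[64, 32])
        with pytest.raises(ValueError):
            PdsNetConfig(fc_count=2)

    @pytest.mark.parametrize(
        "name", ["alexnet", "vgg16", "resnet50", "resnet101", "inceptionv3", "densenet121"]
    )
    def test_all_published_backbone_names_accepted(self, name):
        cfg = BinaryNetConfig(backbone_name=name, input_size=64, fc_width=32)
        assert cfg.patience >= 20
        # constructing the full net is heavy for the wide ones; config suffices
        if name == "alexnet":
            net = build_binary_network(cfg, seed=0)
            x = np.random.default_rng(0).random((1, 64, 64, 3)).astype(np.float32)
            out = net.forward(x)
            assert 0.0 < out[0, 0] < 1.0

    def test_unknown_backbone_rejected(self):
        with pytest.raises(ValueError):
            BinaryNetConfig(backbone_name="mobilenet")

    def test_tiny_binary_trains_one_step(self):
        from pestgs.nn import Adam, bce_loss

        net = build_binary_network(BinaryNetConfig.tiny(), seed=1)
        X = np.stack(
            [generate_leaf_image(f, 64, i).pixels for i, f in enumerate([0.1] * 4 + [0.8] * 4)]
        ).astype(np.float32)
        y = np.array([[0.0]] * 4 + [[1.0]] * 4, dtype=np.float32)
        opt = Adam(net.parameters(), lr=1e-3)
        loss, grad = bce_loss(net.forward(X, train=True, rng=np.random.default_rng(0)), y)
        net.backward(grad)
        opt.step()
        assert np.isfinite(loss)

    def test_freeze_backbone_excludes_parameters(self):
        cfg = PdsNetConfig.tiny()
        cfg.freeze_backbone = True
        net = build_pds_network(cfg, seed=0)
        assert len(net.parameters(trainable_only=True)) < len(net.parameters())


def _toy_regression_net(seed):
    rng = np.random.default_rng(seed)
    return Sequential([Dense(2, 1, rng), ScaledSigmoid(5.0)])


class TestEarlyStopping:
    def test_constant_val_loss_stops_after_patience(self):
        # network output saturates immediately -> no val improvement after 1
        rng = np.random.default_rng(0)
        net = _toy_regression_net(1)
        for p, _ in net.parameters():
            p[...] = 0.0
        X = np.zeros((20, 2), dtype=np.float32)  # constant input, constant output
        y = np.full((20, 1), 2.5, dtype=np.float32)  # loss exactly 0 from epoch 1
        net, rep = train_with_early_stopping(
            net, (X, y), (X, y), loss="mse", patience=5, max_epochs=50, lr=0.0, seed=0
        )
        assert rep.best_epoch == 1
        assert rep.stopped_epoch == 6

    def test_runs_to_max_epochs_when_improving(self):
        rng = np.random.default_rng(2)
        X = rng.random((40, 2)).astype(np.float32)
        y = (1.0 + 2.0 * X[:, :1]).astype(np.float32)
        net = _toy_regression_net(3)
        net, rep = train_with_early_stopping(
            net, (X, y), (X, y), loss="mse", patience=50, max_epochs=20, lr=1e-2, seed=1
        )
        assert rep.stopped_epoch == 20
        assert rep.val_losses[rep.best_epoch - 1] == min(rep.val_losses)

    def test_best_weights_restored(self):
        rng = np.random.default_rng(5)
        X = rng.random((30, 2)).astype(np.float32)
        y = rng.random((30, 1)).astype(np.float32) * 5
        net = _toy_regression_net(4)
        net, rep = train_with_early_stopping(
            net, (X, y), (X, y), loss="mse", patience=3, max_epochs=40, lr=0.05, seed=2
        )
        final_loss = float(np.mean((net.predict(X) - y) ** 2))
        assert final_loss == pytest.approx(rep.best_val_loss, rel=1e-5)

    def test_empty_set_rejected(self):
        net = _toy_regression_net(0)
        X = np.zeros((0, 2), dtype=np.float32)
        with pytest.raises(ValueError):
            train_with_early_stopping(net, (X, X), (X, X))

    def test_loss_curves_reproducible(self):
        rng = np.random.default_rng(8)
        X = rng.random((40, 2)).astype(np.float32)
        y = rng.random((40, 1)).astype(np.float32) * 5
        reps = []
        for _ in range(2):
            net = _toy_regression_net(7)
            _, rep = train_with_early_stopping(
                net, (X[:30], y[:30]), (X[30:], y[30:]), patience=5, max_epochs=15,
                lr=1e-2, seed=9,
            )
            reps.append(rep)
        assert reps[0].train_losses == reps[1].train_losses
        assert reps[0].val_losses == reps[1].val_losses


class TestCrossvalidate:
    def test_folds_partition_data(self):
        from pestgs.phenotyper.training import kfold_indices

        folds = kfold_indices(100, 5, seed=3)
        assert sorted(len(f) for f in folds) == [20] * 5
        assert np.array_equal(np.sort(np.concatenate(folds)), np.arange(100))
        folds2 = kfold_indices(100, 5, seed=3)
        for a, b in zip(folds, folds2):
            np.testing.assert_array_equal(a, b)

    def test_selects_clearly_optimal_learning_rate(self):
        # separable toy task: within a 15-epoch budget only the largest lr
        # can fit, so CV should pick it in nearly all reseeds
        rng = np.random.default_rng(0)
        X = rng.standard_normal((60, 2)).astype(np.float32)
        y = (X[:, 0] > 0).astype(np.float32)

        wins = 0
        for seed in range(10):
            res = crossvalidate(
                _toy_regression_net,
                X,
                y * 5.0,
                k=5,
                lr_grid=(1e-4, 1e-2),
                batch_grid=(32,),
                loss="mse",
                patience=15,
                max_epochs=15,
                seed=seed,
            )
            wins += res["best_lr"] == 1e-2
        assert wins >= 9

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            crossvalidate(_toy_regression_net, np.zeros((10, 2)), np.zeros(10), lr_grid=())


class TestMetrics:
    def test_printed_confusion_counts_reproduce_accuracy(self):
        # 169 correct positives + 176 correct negatives of 362 -> 95.3%
        y_true = np.array([1] * 169 + [0] * 176 + [1] * 9 + [0] * 8)
        y_prob = np.array([0.9] * 169 + [0.1] * 176 + [0.1] * 9 + [0.9] * 8)
        m = classification_metrics(y_true, y_prob)
        assert round(100 * m["accuracy"], 1) == 95.3
        assert m["confusion"][1, 1] == 169 and m["confusion"][0, 0] == 176

    def test_perfect_and_inverted_classifiers(self):
        y = np.array([0, 1, 1, 0])
        assert classification_metrics(y, y.astype(float))["accuracy"] == 1.0
        assert classification_metrics(y, 1.0 - y)["accuracy"] == 0.0

    def test_regression_hand_example(self):
        m = regression_metrics([1, 2, 3], [3, 2, 1])
        assert m["pearson_r"] == pytest.approx(-1.0)
        assert m["mse"] == pytest.approx(8 / 3)

    def test_r_094_implies_r2_088(self):
        # a construction with r ~= 0.94 must report R^2 = r^2 ~= 0.88
        rng = np.random.default_rng(0)
        x = rng.standard_normal(4000)
        y = 0.94 * x + np.sqrt(1 - 0.94**2) * rng.standard_normal(4000)
        m = regression_metrics(x, y)
        assert m["r2"] == pytest.approx(m["pearson_r"] ** 2)
        assert round(m["r2"], 2) == pytest.approx(0.88, abs=0.015)

    def test_metrics_match_bruteforce_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(5, 30))
            y = rng.integers(0, 2, n)
            p = rng.random(n)
            m = classification_metrics(y, p)
            pred = (p >= 0.5).astype(int)
            tp = int(np.sum((y == 1) & (pred == 1)))
            tn = int(np.sum((y == 0) & (pred == 0)))
            fp = int(np.sum((y == 0) & (pred == 1)))
            fn = int(np.sum((y == 1) & (pred == 0)))
            assert m["accuracy"] == pytest.approx((tp + tn) / n)
            prec = tp / (tp + fp) if tp + fp else 0.0
            rec = tp / (tp + fn) if tp + fn else 0.0
            f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
            assert m["f1"] == pytest.approx(f1)

    def test_zero_variance_predictions_rejected(self):
        with pytest.raises(ValueError):
            regression_metrics([1.0, 2.0, 3.0], [2.0, 2.0, 2.0])
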