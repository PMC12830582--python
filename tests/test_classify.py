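"""Classifier: preprocessing, splits, weights, training mechanics, confusion."""

from __future__ import annotations

import numpy as np
import pytest

from dcshape import classify as clf, synthgen as sg
from dcshape.events import CLASS_NAMES, EventClass

ALL_OFF = {k: False for k in ["crop", "rotation", "hflip", "affine",
                              "perspective", "brightness_contrast"]}


class TestPreprocess:
    def test_resizes_any_rectangle_to_square(self):
        out = clf.preprocess(np.zeros((50, 80)), 224)
        assert out.shape == (224, 224)

    def test_constant_image_at_mean_maps_to_zero(self):
        out = clf.preprocess(np.full((30, 30), 117.0), 64,
                             norm_mean=117.0, norm_std=5.0)
        assert np.allclose(out, 0.0)

    def test_deterministic(self):
        img = np.random.default_rng(0).integers(0, 255, (40, 60))
        assert np.array_equal(clf.preprocess(img, 32), clf.preprocess(img, 32))

    def test_zero_size_rejected(self):
        with pytest.raises(ValueError):
            clf.preprocess(np.zeros((0, 10)), 32)


class TestAugment:
    def test_all_toggles_off_is_identity(self, rng):
        img = rng.normal(size=(30, 30))
        assert np.array_equal(clf.augment(img, rng, ALL_OFF), img)

    def test_seeded_stream_reproducible(self):
        img = np.random.default_rng(1).normal(size=(40, 40))
        a = clf.augment(img, np.random.default_rng(5))
        b = clf.augment(img, np.random.default_rng(5))
        assert np.array_equal(a, b)

    def test_hflip_only_with_probability_one_mirrors(self, rng):
        img = np.arange(36.0).reshape(6, 6)
        toggles = dict(ALL_OFF, hflip=True)
        out = clf.augment(img, rng, toggles, p=1.0)
        assert np.array_equal(out, img[:, ::-1])


class TestStratifiedSplit:
    def test_80_20_exact_on_balanced_classes(self):
        images = [np.zeros((8, 8))] * 500
        labels = np.repeat(np.arange(5), 100)
        (ti, tl), (vi, vl) = clf.stratified_split(images, labels, 0.2, 0)
        assert len(vi) == 100 and len(ti) == 400
        for c in range(5):
            assert np.sum(vl == c) == 20
            assert np.sum(tl == c) == 80

    def test_rounding_rule_on_reference_proportions(self):
        counts = [490, 146, 253, 78, 183]
        labels = np.concatenate([np.full(n, i) for i, n in enumerate(counts)])
        images = [np.zeros((4, 4))] * len(labels)
        _, (vi, vl) = clf.stratified_split(images, labels, 0.2, 1)
        got = [int(np.sum(vl == c)) for c in range(5)]
        assert got == [98, 29, 51, 16, 37]

    def test_same_seed_same_split_and_partition(self):
        rng = np.random.default_rng(2)
        images = [rng.normal(size=(5, 5)) for _ in range(40)]
        labels = np.repeat(np.arange(5), 8)
        s1 = clf.stratified_split(images, labels, 0.2, 7)
        s2 = clf.stratified_split(images, labels, 0.2, 7)
        assert np.array_equal(s1[0][1], s2[0][1])
        assert np.array_equal(s1[1][1], s2[1][1])
        assert len(s1[0][0]) + len(s1[1][0]) == 40

    def test_small_class_rejected_by_name(self):
        labels = np.array([0, 0, 0, 3])
        with pytest.raises(ValueError, match="aggregate"):
            clf.stratified_split([np.zeros((4, 4))] * 4, labels, 0.2, 0)


class TestClassWeights:
    def test_equal_counts_unit_weights(self):
        w = clf.class_weights({c: 100 for c in EventClass})
        assert all(v == pytest.approx(1.0) for v in w.values())

    def test_reference_counts_formula(self):
        w = clf.class_weights(sg.REFERENCE_TRAINING_COUNTS)
        n = sum(sg.REFERENCE_TRAINING_COUNTS.values())
        assert n == 11498
        assert w[EventClass.INTACT] == pytest.approx(11498 / (5 * 4904))
        assert w[EventClass.AGGREGATE] == pytest.approx(11498 / (5 * 784))
        assert w[EventClass.INTACT] == pytest.approx(0.469, abs=5e-4)
        assert w[EventClass.AGGREGATE] == pytest.approx(2.933, abs=5e-4)
        # identity: sum_c n_c w_c = N
        total = sum(sg.REFERENCE_TRAINING_COUNTS[c] * w[c] for c in w)
        assert total == pytest.approx(n, rel=1e-12)

    def test_scale_invariance(self):
        w1 = clf.class_weights(sg.REFERENCE_TRAINING_COUNTS)
        w2 = clf.class_weights({c: 2 * n for c, n in
                                sg.REFERENCE_TRAINING_COUNTS.items()})
        for c in w1:
            assert w2[c] == pytest.approx(w1[c], rel=1e-12)

    def test_zero_count_rejected(self):
        with pytest.raises(ValueError, match="dead"):
            clf.class_weights({EventClass.INTACT: 10, EventClass.DEAD: 0})


class TestBuildModel:
    def test_logit_shape_and_param_count(self):
        cfg = clf.TrainConfig(input_size=32, backbone="tiny")
        model = clf.build_model(cfg)
        out = model.forward(np.zeros((2, 1, 32, 32)), train=False)
        assert out.shape == (2, 5)
        assert model.n_parameters() > 0

    def test_tiny_forward_under_one_second(self):
        import time

        cfg = clf.TrainConfig(input_size=64, backbone="tiny")
        model = clf.build_model(cfg)
        x = np.zeros((1, 1, 64, 64))
        t0 = time.time()
        model.forward(x, train=False)
        assert time.time() - t0 < 1.0

    def test_resnet18_backbone_builds(self):
        cfg = clf.TrainConfig(input_size=64, backbone="resnet18")
        model = clf.build_model(cfg)
        out = model.forward(np.zeros((1, 1, 64, 64)), train=False)
        assert out.shape == (1, 5)

    def test_unknown_backbone_rejected(self):
        with pytest.raises(ValueError):
            clf.build_model(clf.TrainConfig(backbone="vgg"))


def _toy_sets(seed=0, n=12):
    images, labels = sg.generate_labeled_arrays(
        {EventClass.INTACT: n, EventClass.DEAD: n}, seed=seed)
    return clf.stratified_split(images, labels, 0.25, seed)


class TestTraining:
    def test_history_bounded_by_epochs(self):
        tr, va = _toy_sets()
        cfg = clf.TrainConfig(input_size=32, epochs=3, batch_size=8,
                              backbone="tiny", seed=0, augmentation=ALL_OFF)
        trained = clf.train(clf.build_model(cfg), tr, va, cfg)
        assert len(trained.history["val_loss"]) <= 3
        assert set(trained.history) >= {"train_loss", "val_loss",
                                        "val_accuracy", "lr"}

    def test_early_stopping_halts_frozen_training(self):
        # lr = 0 freezes the weights (only BN running stats drift), so
        # validation loss plateaus and patience must halt training early
        tr, va = _toy_sets()
        cfg = clf.TrainConfig(input_size=32, epochs=20, batch_size=8,
                              learning_rate=0.0, backbone="tiny", seed=0,
                              early_stop_patience=3, augmentation=ALL_OFF,
                              dropout_p=0.0)
        trained = clf.train(clf.build_model(cfg), tr, va, cfg)
        hist = trained.history["val_loss"]
        assert len(hist) < cfg.epochs
        # the final `patience` epochs brought no improvement over the best
        assert min(hist[-3:]) >= min(hist)

    def test_plateau_reduces_learning_rate(self):
        tr, va = _toy_sets()
        cfg = clf.TrainConfig(input_size=32, epochs=20, batch_size=8,
                              learning_rate=0.0, backbone="tiny", seed=0,
                              early_stop_patience=6, lr_plateau_patience=2,
                              lr_factor=0.5, augmentation=ALL_OFF,
                              dropout_p=0.0)
        trained = clf.train(clf.build_model(cfg), tr, va, cfg)
        assert min(trained.history["lr"]) < cfg.learning_rate + 1e-30 or \
            trained.history["lr"][-1] <= trained.history["lr"][0]

    def test_best_epoch_weights_restored(self):
        tr, va = _toy_sets(seed=1)
        cfg = clf.TrainConfig(input_size=32, epochs=4, batch_size=8,
                              learning_rate=3e-4, backbone="tiny", seed=1,
                              augmentation=ALL_OFF)
        trained = clf.train(clf.build_model(cfg), tr, va, cfg)
        xval = np.stack([clf.preprocess(im, 32, trained.norm_mean,
                                        trained.norm_std)
                         for im in va[0]])[:, None]
        logits = trained.model.forward(xval, train=False)
        from dcshape import nn

        wvec = clf._weight_vector(tr[1])
        vloss, _ = nn.weighted_cross_entropy(logits, va[1], wvec)
        assert vloss == pytest.approx(min(trained.history["val_loss"]),
                                      abs=1e-9)

    def test_divergence_aborts_with_diagnostic(self):
        tr, va = _toy_sets()
        cfg = clf.TrainConfig(input_size=32, epochs=4, batch_size=8,
                              learning_rate=1e160, backbone="tiny", seed=0,
                              augmentation=ALL_OFF)
        with np.errstate(all="ignore"), \
                pytest.raises(RuntimeError, match="diverged"):
            clf.train(clf.build_model(cfg), tr, va, cfg)

    def test_normalization_stats_from_training_set_only(self):
        tr, va = _toy_sets()
        cfg = clf.TrainConfig(input_size=32, epochs=1, batch_size=8,
                              backbone="tiny", seed=0, augmentation=ALL_OFF)
        trained = clf.train(clf.build_model(cfg), tr, va, cfg)
        mean_tr, std_tr = clf._training_stats(tr[0], 32)
        assert trained.norm_mean == mean_tr
        assert trained.norm_std == std_tr
        mean_all, _ = clf._training_stats(tr[0] + va[0], 32)
        assert trained.norm_mean != mean_all


class TestPredictAndConfusion:
    def test_probabilities_sum_to_one(self, tiny_classifier):
        trained, (vi, vl) = tiny_classifier
        labels, probs = trained_labels, trained_probs = clf.predict(trained, vi)
        assert probs.shape == (len(vi), 5)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert set(labels) <= set(CLASS_NAMES)

    def test_eval_mode_deterministic(self, tiny_classifier):
        trained, (vi, _) = tiny_classifier
        _, p1 = clf.predict(trained, vi[:10])
        _, p2 = clf.predict(trained, vi[:10])
        assert np.array_equal(p1, p2)

    def test_save_load_round_trip(self, tiny_classifier, tmp_path):
        trained, (vi, _) = tiny_classifier
        clf.save_classifier(trained, tmp_path / "w.npz", tmp_path / "m.json")
        loaded = clf.load_classifier(tmp_path / "w.npz", tmp_path / "m.json")
        _, p1 = clf.predict(trained, vi[:5])
        _, p2 = clf.predict(loaded, vi[:5])
        assert np.allclose(p1, p2)

    def test_perfect_predictions_diagonal(self):
        y = np.repeat(np.arange(5), 3)
        cm = clf.confusion(y, y)
        assert np.array_equal(cm.counts, np.eye(5, dtype=int) * 3)
        assert np.allclose(cm.per_class_recall, 1.0)

    def test_single_predicted_class_occupies_one_column(self):
        y = np.repeat(np.arange(5), 2)
        pred = np.full(10, 4)  # everything called debris
        cm = clf.confusion(y, pred)
        assert cm.counts[:, 4].sum() == 10
        assert cm.counts[:, :4].sum() == 0

    def test_recall_matches_hand_built_counts(self):
        true_l = [0, 0, 0, 1, 1, 2, 3, 4, 4, 4]
        pred_l = [0, 0, 1, 1, 1, 2, 0, 4, 4, 2]
        cm = clf.confusion(true_l, pred_l)
        assert cm.row_sums.tolist() == [3, 2, 1, 1, 3]
        rec = cm.per_class_recall
        assert rec[0] == pytest.approx(2 / 3)
        assert rec[1] == 1.0 and rec[3] == 0.0
        assert rec[4] == pytest.approx(2 / 3)

    def test_unknown_labels_rejected(self):
        with pytest.raises(ValueError):
            clf.confusion([0, 9], [0, 1])
        with pytest.raises(ValueError):
            clf.confusion(["intact", "mystery"], ["intact", "dead"])
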