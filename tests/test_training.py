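"""Split arithmetic, loss closed forms, and the training loop."""

import math

import numpy as np
import pytest

from acnedx import models, synthetic as syn, training
from acnedx.augment import PreprocSpec, fit_standardizer
from acnedx.nn import Conv2D, Dense, Flatten, MaxPool2D, Sequential
from acnedx.vocab import BINARY_CLASSES


def _dummy_set(n_per_class, k=2):
    pixels = np.zeros((n_per_class * k, 50, 50, 3), dtype=np.uint8)
    labels = np.repeat(np.arange(k), n_per_class)
    return syn.PatchSet(pixels, labels, tuple(f"k{i}" for i in range(k)))


class TestSplit:
    def test_6000_item_classes_split_4800_600_600(self):
        pset = _dummy_set(6000)
        tagged = training.split(pset, training.SplitSpec())
        for ci in range(2):
            m = tagged.labels == ci
            assert (tagged.split[m] == "train").sum() == 4800
            assert (tagged.split[m] == "val").sum() == 600
            assert (tagged.split[m] == "test").sum() == 600

    def test_splits_partition_the_set(self):
        pset = syn.gen_patchset(30, BINARY_CLASSES, 1)
        tagged = training.split(pset, training.SplitSpec(seed=3))
        assert (tagged.split != "").all()
        n = {t: (tagged.split == t).sum() for t in ("train", "val", "test")}
        assert sum(n.values()) == len(pset)

    def test_split_is_reproducible(self):
        pset = syn.gen_patchset(30, BINARY_CLASSES, 1)
        a = training.split(pset, training.SplitSpec(seed=5))
        b = training.split(pset, training.SplitSpec(seed=5))
        assert np.array_equal(a.split, b.split)

    def test_small_class_warns(self):
        pset = _dummy_set(5)
        with pytest.warns(UserWarning):
            training.split(pset, training.SplitSpec())

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            training.SplitSpec(train=0.9, val=0.2, test=0.1)


class TestLosses:
    def test_binary_ce_closed_forms(self):
        assert training.binary_ce(0.5, 0) == pytest.approx(math.log(2), abs=1e-12)
        assert training.binary_ce(0.5, 1) == pytest.approx(math.log(2), abs=1e-12)
        assert training.binary_ce(0.9, 0) == pytest.approx(-math.log(0.1), rel=1e-12)
        assert training.binary_ce(1.0 - 1e-9, 1) < 1e-6

    def test_categorical_ce_closed_forms(self):
        uniform = np.full(7, 1 / 7)
        t = np.eye(7)[2]
        assert training.categorical_ce(uniform, t) == pytest.approx(
            math.log(7), abs=1e-12)
        assert training.categorical_ce(np.eye(7)[4], np.eye(7)[4]) == 0.0

    def test_categorical_ce_decreases_as_correct_mass_grows(self):
        t = np.eye(7)[0]
        losses = []
        for p0 in (0.2, 0.5, 0.8, 0.95):
            y = np.full(7, (1 - p0) / 6)
            y[0] = p0
            losses.append(training.categorical_ce(y, t))
        assert all(a > b for a, b in zip(losses, losses[1:]))

    def test_losses_match_independent_evaluation_on_random_draws(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            p = rng.uniform(1e-6, 1 - 1e-6)
            t = int(rng.integers(2))
            direct = -(t * math.log(p) + (1 - t) * math.log(1 - p))
            assert abs(training.binary_ce(p, t) - direct) < 1e-10
            y = rng.dirichlet(np.ones(7))
            k = int(rng.integers(7))
            onehot = np.eye(7)[k]
            assert abs(training.categorical_ce(y, onehot)
                       - (-math.log(max(y[k], 1e-7)))) < 1e-10

    def test_categorical_ce_rejects_unnormalized_input(self):
        with pytest.raises(ValueError):
            training.categorical_ce(np.full(7, 0.2), np.eye(7)[0])


def _linear_probe_classifier(tagged, seed=0):
    """A cheap flatten+dense model over standardized pixels: enough to
    learn channel statistics quickly."""
    rng = np.random.default_rng(seed)
    net = Sequential([
        Flatten(),
        Dense(7500, 16, rng, activation="relu"),
        Dense(16, 2, rng),
    ], input_shape=(50, 50, 3))
    preproc = fit_standardizer(tagged.subset("train").pixels)
    return models.TrainedClassifier(net, preproc, BINARY_CLASSES)


class TestTrainLoop:
    def test_separable_binary_fixture_reaches_high_validation_accuracy(self):
        pset = training.split(syn.gen_patchset(200, BINARY_CLASSES, 13),
                              training.SplitSpec(seed=13))
        clf, hist = training.train(_linear_probe_classifier(pset), pset,
                                   training.TrainConfig(epochs=10, seed=1337))
        assert len(hist.val_acc) == 10
        assert max(hist.val_acc) >= 0.95

    def test_training_is_deterministic_given_seeds(self):
        pset = training.split(syn.gen_patchset(40, BINARY_CLASSES, 14),
                              training.SplitSpec(seed=14))
        cfg = training.TrainConfig(epochs=3, seed=1337)
        _, h1 = training.train(_linear_probe_classifier(pset, seed=2), pset, cfg)
        _, h2 = training.train(_linear_probe_classifier(pset, seed=2), pset, cfg)
        assert h1.best_epoch == h2.best_epoch
        assert np.allclose(h1.train_loss, h2.train_loss, atol=1e-6)
        assert np.allclose(h1.val_loss, h2.val_loss, atol=1e-6)

    def test_best_epoch_snapshot_is_returned(self):
        pset = training.split(syn.gen_patchset(60, BINARY_CLASSES, 15),
                              training.SplitSpec(seed=15))
        clf, hist = training.train(_linear_probe_classifier(pset, seed=3), pset,
                                   training.TrainConfig(epochs=4, seed=1))
        va = pset.subset("val")
        acc = float((clf.predict(va.pixels) == va.labels).mean())
        assert acc == pytest.approx(hist.val_acc[hist.best_epoch], abs=1e-9)

    def test_label_shuffling_destroys_validation_accuracy(self):
        # leakage guard: with shuffled labels the model must hover at chance
        pset = syn.gen_patchset(100, BINARY_CLASSES, 16)
        rng = np.random.default_rng(16)
        shuffled = syn.PatchSet(pset.pixels, rng.permutation(pset.labels),
                                pset.class_names)
        tagged = training.split(shuffled, training.SplitSpec(seed=16))
        _, hist = training.train(_linear_probe_classifier(tagged, seed=4), tagged,
                                 training.TrainConfig(epochs=5, seed=1337))
        assert 0.4 <= hist.val_acc[hist.best_epoch] <= 0.75

    def test_missing_split_tags_rejected(self):
        pset = syn.gen_patchset(10, BINARY_CLASSES, 17)
        tagged = training.split(pset, training.SplitSpec(seed=17))
        with pytest.raises(ValueError):
            training.train(_linear_probe_classifier(tagged), pset,
                           training.TrainConfig(epochs=1))


def _small_conv_classifier(seed=0):
    rng = np.random.default_rng(seed)
    net = Sequential([
        Conv2D(3, 8, rng, name="conv_a"),
        MaxPool2D("ceil"),
        Conv2D(8, 8, rng, name="conv_b"),
        MaxPool2D("ceil"),
        Flatten(),
        Dense(13 * 13 * 8, 2, rng, name="out"),
    ], input_shape=(50, 50, 3))
    return models.TrainedClassifier(net, PreprocSpec(mode="rescale_01"),
                                    BINARY_CLASSES)


class TestFineTune:
    @pytest.fixture()
    def tagged(self):
        return training.split(syn.gen_patchset(40, BINARY_CLASSES, 18),
                              training.SplitSpec(seed=18))

    def test_zero_unfrozen_layers_leaves_extractor_untouched(self, tagged):
        clf = _small_conv_classifier(seed=5)
        before = [l.W.copy() for l in clf.conv_layers()]
        clf, _ = training.fine_tune(clf, tagged, n_last_conv_layers=0,
                                    epochs=1)
        for w0, layer in zip(before, clf.conv_layers()):
            assert np.array_equal(w0, layer.W)

    def test_only_last_conv_layers_update(self, tagged):
        clf = _small_conv_classifier(seed=6)
        w_frozen = clf.conv_layers()[0].W.copy()
        w_tuned = clf.conv_layers()[1].W.copy()
        clf, _ = training.fine_tune(clf, tagged, n_last_conv_layers=1,
                                    epochs=1)
        assert np.array_equal(w_frozen, clf.conv_layers()[0].W)
        assert not np.array_equal(w_tuned, clf.conv_layers()[1].W)

    def test_fine_tune_does_not_degrade_validation_accuracy(self, tagged):
        clf = _small_conv_classifier(seed=7)
        clf, _ = training.train(clf, tagged,
                                training.TrainConfig(epochs=3, seed=1))
        va = tagged.subset("val")
        before = (clf.predict(va.pixels) == va.labels).mean()
        clf, _ = training.fine_tune(clf, tagged, n_last_conv_layers=1,
                                    lr=0.001, epochs=2)
        after = (clf.predict(va.pixels) == va.labels).mean()
        assert after >= before - 0.02

    def test_excess_layer_count_rejected(self, tagged):
        with pytest.raises(ValueError):
            training.fine_tune(_small_conv_classifier(), tagged,
                               n_last_conv_layers=5)

    def test_out_of_range_learning_rate_rejected(self, tagged):
        with pytest.raises(ValueError):
            training.fine_tune(_small_conv_classifier(), tagged,
                               n_last_conv_layers=1, lr=0.1)
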