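"""Shared fixtures.

The two trained classifiers are expensive (minutes of CPU), so they are
session-scoped and shared between the pipeline tests and the
end-to-end/acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from acnedx import models, synthetic, training
from acnedx.augment import PreprocSpec, fit_standardizer
from acnedx.evaluation import ScoredBatch, roc_curve, youden_best
from acnedx.vocab import BINARY_CLASSES, NON_SKIN, SEVEN_CLASSES

# desk-scale study conditions: binary task trains 200 patches/class for
# 20 epochs (seed 1337); seven-class task trains 150 patches/class for
# 12 epochs with the same protocol
BINARY_N_PER_CLASS = 200
BINARY_EPOCHS = 20
SEVEN_N_PER_CLASS = 150
SEVEN_EPOCHS = 12
DATA_SEED = 7


@pytest.fixture(scope="session")
def binary_data() -> synthetic.PatchSet:
    pset = synthetic.gen_patchset(BINARY_N_PER_CLASS, BINARY_CLASSES,
                                  DATA_SEED)
    return training.split(pset, training.SplitSpec())


@pytest.fixture(scope="session")
def seven_data() -> synthetic.PatchSet:
    pset = synthetic.gen_patchset(SEVEN_N_PER_CLASS, SEVEN_CLASSES,
                                  DATA_SEED + 1)
    return training.split(pset, training.SplitSpec())


@pytest.fixture(scope="session")
def binary_model(binary_data) -> models.TrainedClassifier:
    """Small CNN trained on the synthetic skin/non-skin task, with the
    Youden-optimal validation threshold installed."""
    net = models.build_small_cnn(n_classes=2, seed=0)
    clf = models.TrainedClassifier(net, PreprocSpec(mode="rescale_01"),
                                   BINARY_CLASSES)
    clf, _ = training.train(clf, binary_data,
                            training.TrainConfig(epochs=BINARY_EPOCHS,
                                                 seed=1337))
    va = binary_data.subset("val")
    probs = clf.predict_proba(va.pixels)[:, 0]
    batch = ScoredBatch(probs, (va.labels == 0).astype(int))
    _, thr = youden_best(roc_curve(batch))
    clf.decision_threshold = float(min(max(thr, 1e-6), 1 - 1e-6))
    return clf


@pytest.fixture(scope="session")
def seven_model(seven_data) -> models.TrainedClassifier:
    """Seven-class CNN (small-CNN body, 7-wide output) trained on the
    synthetic lesion classes with global standardization."""
    preproc = fit_standardizer(seven_data.subset("train").pixels)
    net = models.build_small_cnn(n_classes=7, seed=0)
    clf = models.TrainedClassifier(net, preproc, SEVEN_CLASSES)
    clf, _ = training.train(clf, seven_data,
                            training.TrainConfig(epochs=SEVEN_EPOCHS,
                                                 seed=1337))
    return clf


def make_face_truth(seed: int = 5) -> np.ndarray:
    """10x10 tile truth with 40 non-skin, 36 normal, 12 blackhead and
    12 pustule tiles (skin fractions 0.6 / 0.2 / 0.2)."""
    codes = ([NON_SKIN] * 40 + [SEVEN_CLASSES.index("normal")] * 36
             + [SEVEN_CLASSES.index("blackhead")] * 12
             + [SEVEN_CLASSES.index("pustule")] * 12)
    rng = np.random.default_rng(seed)
    return rng.permutation(np.array(codes)).reshape(10, 10)


@pytest.fixture(scope="session")
def mixed_face() -> synthetic.FaceFixture:
    return synthetic.gen_face(make_face_truth(), seed=123)
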