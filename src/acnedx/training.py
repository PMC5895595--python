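"""Data splitting, cross-entropy losses, and the training protocol.

The published protocol is followed: stratified 80/10/10 splits, Adam
(lr 0.001, beta1 0.9, beta2 0.999), batch size 64, 50 epochs, seed
1337, with the best epoch chosen by validation accuracy; an optional
SGD fine-tuning pass updates only the last few convolutional layers of
the extractor.  Epoch counts and sample sizes are configurable so the
same loop runs at desk scale on synthetic fixtures.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .augment import preprocess
from .models import TrainedClassifier
from .nn import Conv2D, make_optimizer, softmax, softmax_ce
from .synthetic import PatchSet

EPS_CLIP = 1e-7


@dataclass
class SplitSpec:
    train: float = 0.8
    val: float = 0.1
    test: float = 0.1
    seed: int = 1337

    def __post_init__(self):
        if min(self.train, self.val, self.test) <= 0:
            raise ValueError("split fractions must be positive")
        if abs(self.train + self.val + self.test - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


@dataclass
class TrainConfig:
    optimizer: str = "adam"
    learning_rate: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 64
    epochs: int = 50
    seed: int = 1337

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    best_epoch: int = 0   # 0-based index into the records


# ---------------------------------------------------------------------------
# splitting

def split(pset: PatchSet, spec: SplitSpec) -> PatchSet:
    """Stratified train/val/test tagging, reproducible given the seed.

    Within each class, boundaries are placed by cumulative rounding of
    the fractions, so a 6000-item class at 0.8/0.1/0.1 yields exactly
    4800/600/600.
    """
    rng = np.random.default_rng(spec.seed)
    tags = np.full(len(pset), "", dtype="<U5")
    for ci in range(len(pset.class_names)):
        idx = np.flatnonzero(pset.labels == ci)
        if 0 < len(idx) < 10:
            warnings.warn(
                f"class {pset.class_names[ci]!r} has only {len(idx)} items; "
                "split counts are proportionally rounded", stacklevel=2)
        perm = rng.permutation(idx)
        n = len(perm)
        c1 = round(spec.train * n)
        c2 = round((spec.train + spec.val) * n)
        tags[perm[:c1]] = "train"
        tags[perm[c1:c2]] = "val"
        tags[perm[c2:]] = "test"
    return PatchSet(pset.pixels, pset.labels, pset.class_names, tags)


# ---------------------------------------------------------------------------
# losses (reference scalar forms; the training loop uses the equivalent
# batched softmax cross-entropy on logits)

def binary_ce(p: float, t: int) -> float:
    """Binary cross-entropy -t*log p - (1-t)*log(1-p), natural log,
    with p clipped to [1e-7, 1 - 1e-7]."""
    if t not in (0, 1):
        raise ValueError("binary label must be 0 or 1")
    p = min(max(float(p), EPS_CLIP), 1.0 - EPS_CLIP)
    return -t * math.log(p) - (1 - t) * math.log(1.0 - p)


def categorical_ce(y, t) -> float:
    """Categorical cross-entropy -sum_i t_i log y_i for a one-hot t."""
    y = np.asarray(y, dtype=float)
    t = np.asarray(t, dtype=float)
    if y.shape != t.shape:
        raise ValueError("probability and target vectors must align")
    if abs(y.sum() - 1.0) > 1e-6:
        raise ValueError("probability vector must be normalized")
    if not (np.isin(t, (0.0, 1.0)).all() and t.sum() == 1.0):
        raise ValueError("target must be one-hot")
    return float(-(t * np.log(np.clip(y, EPS_CLIP, 1.0))).sum())


# ---------------------------------------------------------------------------
# the training loop

def _eval_batches(net, x, y, batch_size=64):
    loss_sum, correct = 0.0, 0
    for i in range(0, len(x), batch_size):
        logits = net.forward(x[i:i + batch_size])
        loss, _ = softmax_ce(logits, y[i:i + batch_size])
        loss_sum += loss * len(logits)
        correct += int((logits.argmax(axis=1) == y[i:i + batch_size]).sum())
    return loss_sum / len(x), correct / len(x)


def train(classifier: TrainedClassifier, data: PatchSet,
          config: TrainConfig | None = None) -> tuple[TrainedClassifier, TrainHistory]:
    """Mini-batch training with best-epoch selection.

    ``data`` must carry ``train`` and ``val`` split tags.  Shuffling,
    dropout, and weight initialization are all seeded, so two runs with
    the same configuration and data produce identical histories.  The
    returned classifier holds the weights of the epoch with the highest
    validation accuracy (earliest epoch on ties).
    """
    config = config or TrainConfig()
    tr, va = data.subset("train"), data.subset("val")
    if len(tr) == 0 or len(va) == 0:
        raise ValueError("data must contain non-empty train and val splits")
    x_tr = preprocess(tr.pixels, classifier.preproc)
    y_tr = tr.labels
    x_va = preprocess(va.pixels, classifier.preproc)
    y_va = va.labels

    net = classifier.network
    opt = make_optimizer(config.optimizer, config.learning_rate,
                         config.beta1, config.beta2)
    rng = np.random.default_rng(config.seed)
    params, grads_ref = net.trainable_params()

    history = TrainHistory()
    best_acc, best_weights = -1.0, net.get_weights()
    for epoch in range(config.epochs):
        order = rng.permutation(len(x_tr))
        losses = []
        for i in range(0, len(order), config.batch_size):
            bi = order[i:i + config.batch_size]
            logits = net.forward(x_tr[bi], train=True, rng=rng)
            loss, dlogits = softmax_ce(logits, y_tr[bi])
            net.backward(dlogits)
            _, grads = net.trainable_params()
            opt.step(params, grads)
            losses.append(loss)
        vl, vacc = _eval_batches(net, x_va, y_va)
        history.train_loss.append(float(np.mean(losses)))
        history.val_loss.append(vl)
        history.val_acc.append(vacc)
        if vacc > best_acc:
            best_acc = vacc
            best_weights = net.get_weights()
            history.best_epoch = epoch
    net.set_weights(best_weights)
    return classifier, history


def fine_tune(classifier: TrainedClassifier, data: PatchSet,
              n_last_conv_layers: int, lr: float = 0.001,
              epochs: int = 5, batch_size: int = 64,
              seed: int = 1337) -> tuple[TrainedClassifier, TrainHistory]:
    """SGD fine-tuning of the last ``n_last_conv_layers`` convolutional
    layers of the extractor together with the head; all other extractor
    layers stay frozen.  ``lr`` follows the published [0.001, 0.01]
    interval."""
    if not 0.001 <= lr <= 0.01:
        raise ValueError("fine-tune learning rate must lie in [0.001, 0.01]")
    convs = classifier.conv_layers()
    if not convs:
        raise ValueError("classifier has no convolutional extractor")
    if n_last_conv_layers > len(convs):
        raise ValueError(f"asked to unfreeze {n_last_conv_layers} conv "
                         f"layers but the extractor has {len(convs)}")
    boundary = classifier.head_start or len(classifier.network.layers)
    saved = {}
    for li, layer in enumerate(classifier.network.layers):
        saved[li] = layer.trainable
        if isinstance(layer, Conv2D) and li < boundary:
            layer.trainable = False
    for layer in convs[len(convs) - n_last_conv_layers:] if n_last_conv_layers else []:
        layer.trainable = True
    try:
        cfg = TrainConfig(optimizer="sgd", learning_rate=lr,
                          batch_size=batch_size, epochs=epochs, seed=seed)
        classifier, history = train(classifier, data, cfg)
    finally:
        for li, layer in enumerate(classifier.network.layers):
            layer.trainable = saved[li]
    return classifier, history


__all__ = [
    "SplitSpec", "TrainConfig", "TrainHistory",
    "split", "binary_ce", "categorical_ce", "train", "fine_tune",
    "EPS_CLIP",
]
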