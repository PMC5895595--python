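"""Model architectures and the trained-classifier container.

Three architectures are defined:

* the self-constructed small CNN — Conv64, Conv64, pool, Conv64, pool,
  dropout, flatten, dense-128, dropout, dense-N.  With ceiling-mode
  2x2 pooling on a 50x50 input the spatial trace is 50 -> 25 -> 13,
  so the flatten width is 13*13*64 = 10816;
* the headless VGG16-shaped extractor — thirteen 3x3 convolutions in
  blocks of widths (64, 128, 256, 512, 512) with five floor-mode
  poolings, collapsing 50 -> 25 -> 12 -> 6 -> 3 -> 1 and emitting a
  512-dimensional feature vector.  ImageNet weights are an optional
  pluggable asset (loaded from a checkpoint); the architecture runs
  with random initialization otherwise;
* the dense classifier head — flatten, dense-256 (ReLU), dropout,
  dense-N — attached either to exported feature vectors or, composed,
  to the extractor itself.

The two pooling-rounding modes differ deliberately: each is the unique
conventional geometry consistent with its printed widths (10816 and
512 x 1 x 1 respectively).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .augment import PreprocSpec, preprocess
from .nn import Conv2D, Dense, Dropout, Flatten, MaxPool2D, Sequential
from .synthetic import PATCH_SIZE

FEATURE_DIM = 512
_VGG_BLOCKS = ((64, 2), (128, 2), (256, 3), (512, 3), (512, 3))
DROPOUT_RATE = 0.5


def build_small_cnn(n_classes: int = 2, seed: int = 0,
                    input_size: int = PATCH_SIZE) -> Sequential:
    """The self-constructed CNN.  ``n_classes=2`` is the published
    binary form; a 7-wide terminal dense layer adapts it to the
    seven-class task at desk scale."""
    rng = np.random.default_rng(seed)
    s = input_size
    flat = ((s + 1) // 2 + 1) // 2  # two ceiling-mode 2x2 poolings
    return Sequential([
        Conv2D(3, 64, rng, name="block1_conv1"),
        Conv2D(64, 64, rng, name="block1_conv2"),
        MaxPool2D("ceil", name="block1_pool"),
        Conv2D(64, 64, rng, name="block2_conv1"),
        MaxPool2D("ceil", name="block2_pool"),
        Dropout(DROPOUT_RATE, name="dropout1"),
        Flatten(name="flatten1"),
        Dense(flat * flat * 64, 128, rng, activation="relu", name="dense1"),
        Dropout(DROPOUT_RATE, name="dropout2"),
        Dense(128, n_classes, rng, name="dense2"),
    ], input_shape=(s, s, 3))


def build_extractor(kind: str, seed: int = 0,
                    input_size: int = PATCH_SIZE) -> Sequential:
    """Feature extractor: ``'vgg16_headless'`` (512-d vectors) or
    ``'small_cnn_features'`` (the small CNN up to its 128-d dense
    representation)."""
    rng = np.random.default_rng(seed)
    if kind == "vgg16_headless":
        layers = []
        c_in = 3
        for b, (width, n_conv) in enumerate(_VGG_BLOCKS, start=1):
            for i in range(1, n_conv + 1):
                layers.append(Conv2D(c_in, width, rng,
                                     name=f"block{b}_conv{i}"))
                c_in = width
            layers.append(MaxPool2D("floor", name=f"block{b}_pool"))
        layers.append(Flatten(name="flatten"))
        return Sequential(layers, input_shape=(input_size, input_size, 3))
    if kind == "small_cnn_features":
        net = build_small_cnn(seed=seed, input_size=input_size)
        return Sequential(net.layers[:-2], net.input_shape)
    raise ValueError(f"unknown extractor kind {kind!r}")


def build_head(n_classes: int, in_dim: int = FEATURE_DIM,
               seed: int = 0) -> Sequential:
    """Dense classifier head over exported feature vectors."""
    if n_classes not in (2, 7):
        raise ValueError("head supports 2 or 7 classes")
    rng = np.random.default_rng(seed)
    return Sequential([
        Flatten(name="flatten1"),
        Dense(in_dim, 256, rng, activation="relu", name="dense1"),
        Dropout(DROPOUT_RATE, name="dropout1"),
        Dense(256, n_classes, rng, name="dense2"),
    ], input_shape=(in_dim,))


def compose_networks(extractor: Sequential, head: Sequential) -> tuple[Sequential, int]:
    """Stack extractor + head into one network; returns it and the
    index of the first head layer (the freeze boundary)."""
    if int(np.prod(extractor.output_shape())) != head.layers[1].n_in:
        raise ValueError("extractor output does not match head input")
    net = Sequential(extractor.layers + head.layers, extractor.input_shape)
    return net, len(extractor.layers)


@dataclass
class TrainedClassifier:
    """A network plus everything needed to apply it: the preprocessing
    it was trained with, its class vocabulary, and (for the binary
    task) the operating threshold on the positive-class probability."""

    network: Sequential
    preproc: PreprocSpec
    class_names: tuple[str, ...]
    decision_threshold: float | None = None
    head_start: int = 0   # first head layer; layers before it are the extractor

    def __post_init__(self):
        if self.decision_threshold is not None and not (
                0 < self.decision_threshold < 1):
            raise ValueError("decision threshold must lie in (0, 1)")

    def predict_proba(self, pixels: np.ndarray,
                      batch_size: int = 64) -> np.ndarray:
        """Class probabilities for a stack of raw uint8 patches."""
        x = preprocess(pixels, self.preproc)
        return self.network.predict_proba(x, batch_size=batch_size)

    def predict(self, pixels: np.ndarray) -> np.ndarray:
        return self.predict_proba(pixels).argmax(axis=1)

    def conv_layers(self) -> list[Conv2D]:
        return [l for l in self.network.layers[:self.head_start or None]
                if isinstance(l, Conv2D)]


def extract_features(extractor: Sequential, pixels: np.ndarray,
                     preproc: PreprocSpec, batch_size: int = 64) -> np.ndarray:
    """One feature vector per patch, order preserved."""
    if pixels.ndim != 4 or pixels.shape[1:3] != extractor.input_shape[:2]:
        raise ValueError(f"expected (n, {extractor.input_shape[0]}, "
                         f"{extractor.input_shape[1]}, 3) pixels, "
                         f"got {pixels.shape}")
    x = preprocess(pixels, preproc)
    out = [extractor.forward(x[i:i + batch_size])
           for i in range(0, len(x), batch_size)]
    return np.concatenate(out, axis=0)


# ---------------------------------------------------------------------------
# checkpoints: npz weights + json metadata

def save_classifier(clf: TrainedClassifier, path: str | Path,
                    arch: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    weights = clf.network.get_weights()
    np.savez(path.with_suffix(".npz"),
             **{f"w{i}": w for i, w in enumerate(weights)})
    meta = {
        "arch": arch or {},
        "preproc": {"mode": clf.preproc.mode, "mean": clf.preproc.mean,
                    "std": clf.preproc.std},
        "class_names": list(clf.class_names),
        "decision_threshold": clf.decision_threshold,
        "head_start": clf.head_start,
        "summary": clf.network.summary(),
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_classifier(path: str | Path) -> TrainedClassifier:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    arch = meta["arch"]
    kind = arch.get("kind", "small_cnn")
    if kind == "small_cnn":
        net = build_small_cnn(n_classes=arch.get("n_classes", 2))
    elif kind == "extractor_head":
        ext = build_extractor(arch.get("extractor", "vgg16_headless"))
        head = build_head(arch.get("n_classes", 2),
                          in_dim=int(np.prod(ext.output_shape())))
        net, _ = compose_networks(ext, head)
    else:
        raise ValueError(f"unknown architecture kind {kind!r}")
    with np.load(path.with_suffix(".npz")) as z:
        net.set_weights([z[f"w{i}"] for i in range(len(z.files))])
    p = meta["preproc"]
    return TrainedClassifier(
        network=net,
        preproc=PreprocSpec(mode=p["mode"], mean=p["mean"], std=p["std"]),
        class_names=tuple(meta["class_names"]),
        decision_threshold=meta["decision_threshold"],
        head_start=meta["head_start"],
    )


__all__ = [
    "FEATURE_DIM", "DROPOUT_RATE",
    "build_small_cnn", "build_extractor", "build_head", "compose_networks",
    "TrainedClassifier", "extract_features",
    "save_classifier", "load_classifier",
]
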