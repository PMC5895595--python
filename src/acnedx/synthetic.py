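"""Synthetic patch and face fixtures with known ground truth.

The clinical images behind the original acne study are private, so the
pipeline is exercised on generated 50x50 RGB patches whose classes are
separable by low-order color and shape statistics: lesion classes are
drawn as discs of class-specific color and size over a noisy beige skin
base, and non-skin is either dark striped hair texture or a saturated
uniform background.  Composite 500x500 "faces" are assembled from a
10x10 grid of such patches with per-tile ground truth, emulating the
sliding-window diagnosis input.

Recipes are deliberately simple, not photorealistic: they guarantee
that a small CNN trained on one CPU can separate the classes, which is
what makes the downstream training, evaluation, and diagnosis tests
meaningful.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .vocab import (BINARY_CLASSES, FACE_CLASSES, NON_SKIN, SEVEN_CLASSES,
                    canonical_class)

PATCH_SIZE = 50

# beige skin base (R, G, B) and per-pixel noise scale
_SKIN_BASE = np.array([200.0, 160.0, 140.0])
_SKIN_NOISE_SD = 10.0
# noise is truncated at +/-39 so every skin pixel stays within 4 sd of base
_SKIN_NOISE_CLIP = 39.0


@dataclass
class Patch:
    """A 50x50 RGB image, the atomic classification unit."""

    pixels: np.ndarray          # (50, 50, 3) uint8
    label: int | None = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.shape != (PATCH_SIZE, PATCH_SIZE, 3):
            raise ValueError(f"patch must be {PATCH_SIZE}x{PATCH_SIZE}x3, "
                             f"got {self.pixels.shape}")


@dataclass
class PatchSet:
    """A labeled collection of patches with optional split tags."""

    pixels: np.ndarray           # (n, 50, 50, 3) uint8
    labels: np.ndarray           # (n,) int
    class_names: tuple[str, ...]
    split: np.ndarray = field(default=None)  # (n,) of '', 'train', 'val', 'test'

    def __post_init__(self):
        if self.split is None:
            self.split = np.full(len(self.labels), "", dtype="<U5")
        if not (len(self.pixels) == len(self.labels) == len(self.split)):
            raise ValueError("pixels, labels and split must align")
        if len(self.labels) and not (
                (0 <= self.labels).all() and (self.labels < len(self.class_names)).all()):
            raise ValueError("labels must index class_names")

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, tag: str) -> "PatchSet":
        m = self.split == tag
        return PatchSet(self.pixels[m], self.labels[m], self.class_names,
                        self.split[m].copy())

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=len(self.class_names))


@dataclass
class FaceFixture:
    """A composite face image with per-tile ground truth.

    ``tile_truth`` codes 0..6 are the seven lesion/skin classes and 7 is
    non-skin (``vocab.FACE_CLASSES``).
    """

    image: np.ndarray            # (50*rows, 50*cols, 3) uint8
    tile_truth: np.ndarray       # (rows, cols) int codes into FACE_CLASSES
    recipe_seed: int

    def __post_init__(self):
        r, c = self.tile_truth.shape
        if self.image.shape != (r * PATCH_SIZE, c * PATCH_SIZE, 3):
            raise ValueError("image dimensions must be 50x the truth grid")


# ---------------------------------------------------------------------------
# drawing primitives

def _disc_mask(cy: float, cx: float, r: float) -> np.ndarray:
    yy, xx = np.mgrid[0:PATCH_SIZE, 0:PATCH_SIZE]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r


def _noise(rng, sd: float, clip: float, shape=(PATCH_SIZE, PATCH_SIZE, 3)):
    return np.clip(rng.normal(0.0, sd, shape), -clip, clip)


def _skin_canvas(rng) -> np.ndarray:
    return _SKIN_BASE + _noise(rng, _SKIN_NOISE_SD, _SKIN_NOISE_CLIP)


def _paint_disc(img, mask, color, rng, sd=5.0, clip=15.0):
    noise = _noise(rng, sd, clip)
    img[mask] = np.asarray(color, dtype=float) + noise[mask]


def _hsv_to_rgb(h: float, s: float, v: float) -> np.ndarray:
    i = int(h * 6) % 6
    f = h * 6 - int(h * 6)
    p, q, t = v * (1 - s), v * (1 - f * s), v * (1 - (1 - f) * s)
    rgb = [(v, t, p), (q, v, p), (p, v, t), (p, q, v), (t, p, v), (v, p, q)][i]
    return np.array(rgb) * 255.0


# ---------------------------------------------------------------------------
# class recipes

def _recipe_normal(rng):
    return _skin_canvas(rng)


def _recipe_papule(rng):
    img = _skin_canvas(rng)
    r = rng.uniform(5, 8)
    cy, cx = rng.uniform(15, 35, 2)
    _paint_disc(img, _disc_mask(cy, cx, r), (190, 70, 70), rng)
    return img


def _recipe_cyst(rng):
    img = _skin_canvas(rng)
    r = rng.uniform(15, 20)
    cy, cx = rng.uniform(22, 28, 2)
    _paint_disc(img, _disc_mask(cy, cx, r), (120, 30, 45), rng)
    return img


def _recipe_blackhead(rng):
    img = _skin_canvas(rng)
    n_dots = int(rng.integers(1, 4))
    centers: list[tuple[float, float]] = []
    while len(centers) < n_dots:
        cy, cx = rng.uniform(6, 44, 2)
        if all((cy - y) ** 2 + (cx - x) ** 2 >= 10 ** 2 for y, x in centers):
            centers.append((cy, cx))
    for cy, cx in centers:
        r = rng.uniform(2.0, 2.95)  # rasterized area 13-25 px per dot
        _paint_disc(img, _disc_mask(cy, cx, r), (30, 25, 20), rng)
    return img


def _recipe_pustule(rng):
    img = _skin_canvas(rng)
    r = rng.uniform(6, 9)
    cy, cx = rng.uniform(15, 35, 2)
    _paint_disc(img, _disc_mask(cy, cx, r), (190, 70, 70), rng)
    _paint_disc(img, _disc_mask(cy, cx, 0.45 * r), (240, 235, 220), rng)
    return img


def _recipe_whitehead(rng):
    img = _skin_canvas(rng)
    r = rng.uniform(3, 5)
    cy, cx = rng.uniform(10, 40, 2)
    _paint_disc(img, _disc_mask(cy, cx, r), (245, 240, 225), rng)
    return img


def _recipe_nodule(rng):
    img = _skin_canvas(rng)
    r = rng.uniform(19, 22)  # covers >40% of the patch
    cy, cx = rng.uniform(22, 28, 2)
    _paint_disc(img, _disc_mask(cy, cx, r), (160, 105, 95), rng, sd=6, clip=18)
    return img


def _recipe_non_skin(rng):
    if rng.random() < 0.5:  # dark hair texture with high-frequency stripes
        base = np.array([45.0, 38.0, 32.0])
        col = np.arange(PATCH_SIZE)[None, :]
        row = np.arange(PATCH_SIZE)[:, None]
        phase = rng.uniform(0, 2 * np.pi)
        slope = rng.uniform(-0.3, 0.3)
        stripes = 18.0 * np.sin(2 * np.pi * 0.45 * (col + slope * row) + phase)
        img = base + stripes[:, :, None] + _noise(rng, 6.0, 18.0)
        return np.clip(img, 5, 79)  # all channels stay below 80
    # saturated uniform cool-hued background (green through blue), the
    # typical clinical backdrop; never overlaps warm skin tones
    color = _hsv_to_rgb(rng.uniform(0.3, 0.7), rng.uniform(0.75, 0.95),
                        rng.uniform(0.55, 0.85))
    return color + _noise(rng, 3.0, 9.0)


_RECIPES = {
    "papule": _recipe_papule,
    "cyst": _recipe_cyst,
    "blackhead": _recipe_blackhead,
    "normal": _recipe_normal,
    "pustule": _recipe_pustule,
    "whitehead": _recipe_whitehead,
    "nodule": _recipe_nodule,
    "non_skin": _recipe_non_skin,
}


# ---------------------------------------------------------------------------
# public operations

def gen_patch(class_id: str | int, rng: np.random.Generator) -> Patch:
    """Generate one labeled patch following the class recipe.

    ``class_id`` may be a seven-class name, a ``c0``..``c6`` alias,
    ``'non_skin'``, or ``'skin'``.  The binary task's skin class mixes
    normal and diseased skin (a uniform draw over the seven classes),
    mirroring the composition of the study's skin set.
    """
    if isinstance(class_id, str) and class_id == "skin":
        code = int(rng.integers(len(SEVEN_CLASSES)))
    else:
        code = canonical_class(class_id, FACE_CLASSES)
    img = _RECIPES[FACE_CLASSES[code]](rng)
    return Patch(np.clip(np.rint(img), 0, 255).astype(np.uint8))


def gen_patchset(n_per_class: int, classes: tuple[str, ...] | list[str],
                 seed: int) -> PatchSet:
    """Balanced, reproducible patch set: ``n_per_class`` per class, in
    class-blocked order."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    classes = tuple(classes)
    rng = np.random.default_rng(seed)
    pixels = np.empty((n_per_class * len(classes), PATCH_SIZE, PATCH_SIZE, 3),
                      dtype=np.uint8)
    labels = np.empty(n_per_class * len(classes), dtype=np.int64)
    k = 0
    for ci, cname in enumerate(classes):
        for _ in range(n_per_class):
            pixels[k] = gen_patch(cname, rng).pixels
            labels[k] = ci
            k += 1
    return PatchSet(pixels, labels, classes)


def gen_face(tile_truth, seed: int) -> FaceFixture:
    """Assemble a composite face from per-tile recipes, row-major.

    Each tile uses its own generator seeded ``seed + row*cols + col`` so
    faces are reproducible tile by tile.
    """
    truth = np.asarray(tile_truth)
    if truth.ndim != 2:
        raise ValueError(f"tile_truth must be a 2-D grid, got shape {truth.shape}")
    rows, cols = truth.shape
    codes = np.empty((rows, cols), dtype=np.int64)
    for r in range(rows):
        for c in range(cols):
            codes[r, c] = canonical_class(truth[r, c].item()
                                          if hasattr(truth[r, c], "item")
                                          else truth[r, c], FACE_CLASSES)
    image = np.empty((rows * PATCH_SIZE, cols * PATCH_SIZE, 3), dtype=np.uint8)
    for r in range(rows):
        for c in range(cols):
            tile_rng = np.random.default_rng(seed + r * cols + c)
            patch = gen_patch(int(codes[r, c]), tile_rng)
            image[r * PATCH_SIZE:(r + 1) * PATCH_SIZE,
                  c * PATCH_SIZE:(c + 1) * PATCH_SIZE] = patch.pixels
    return FaceFixture(image, codes, seed)


# ---------------------------------------------------------------------------
# disk I/O (PNG directories, CSV truth)

def save_patchset(pset: PatchSet, out_dir: str | Path) -> None:
    """One subdirectory per class; patches as zero-padded PNGs.  Split
    tags, when assigned, go to ``splits.csv``."""
    out = Path(out_dir)
    for ci, cname in enumerate(pset.class_names):
        (out / cname).mkdir(parents=True, exist_ok=True)
    width = len(str(max(len(pset) - 1, 1)))
    for i in range(len(pset)):
        cname = pset.class_names[pset.labels[i]]
        Image.fromarray(pset.pixels[i]).save(
            out / cname / f"{i:0{width}d}.png")
    if (pset.split != "").any():
        with open(out / "splits.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["index", "class", "split"])
            for i in range(len(pset)):
                w.writerow([i, pset.class_names[pset.labels[i]], pset.split[i]])


def load_patchset(in_dir: str | Path,
                  class_names: tuple[str, ...] | None = None) -> PatchSet:
    root = Path(in_dir)
    if class_names is None:
        class_names = tuple(sorted(p.name for p in root.iterdir() if p.is_dir()))
    pixels, labels = [], []
    for ci, cname in enumerate(class_names):
        for f in sorted((root / cname).glob("*.png")):
            pixels.append(np.asarray(Image.open(f).convert("RGB")))
            labels.append(ci)
    return PatchSet(np.stack(pixels), np.asarray(labels), tuple(class_names))


def save_face(face: FaceFixture, out_dir: str | Path, stem: str = "face") -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    Image.fromarray(face.image).save(out / f"{stem}.png")
    with open(out / f"{stem}_truth.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["row", "col", "class"])
        rows, cols = face.tile_truth.shape
        for r in range(rows):
            for c in range(cols):
                w.writerow([r, c, FACE_CLASSES[face.tile_truth[r, c]]])


__all__ = [
    "PATCH_SIZE", "Patch", "PatchSet", "FaceFixture",
    "gen_patch", "gen_patchset", "gen_face",
    "save_patchset", "load_patchset", "save_face",
    "SEVEN_CLASSES", "BINARY_CLASSES", "FACE_CLASSES", "NON_SKIN",
]
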