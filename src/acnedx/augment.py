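"""Affine augmentation and pixel preprocessing.

The four elementary transforms (rotation, shift, shear, zoom) are
expressed as 3x3 homogeneous matrices acting on 1-based (row, col)
pixel coordinates, with offsets constructed so the image center
((h+1)/2, (w+1)/2) is a fixed point of rotation, shear and zoom.
Resampling is inverse-mapped (each output pixel pulls from the input)
with bilinear or nearest interpolation.

Preprocessing follows the two schemes used by the classifiers:
rescaling to [0, 1] by dividing by 255, or global standardization by a
single scalar mean and standard deviation of the training split.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .synthetic import PatchSet


# ---------------------------------------------------------------------------
# configuration

@dataclass
class AffineParams:
    theta: float = 0.0    # rotation, radians
    tx: float = 0.0       # shift along height, pixels
    ty: float = 0.0       # shift along width, pixels
    shear: float = 0.0    # radians
    zx: float = 1.0       # zoom along height
    zy: float = 1.0       # zoom along width
    flip: bool = False    # horizontal flip

    def __post_init__(self):
        if self.zx <= 0 or self.zy <= 0:
            raise ValueError("zoom factors must be positive")


@dataclass
class AugmentConfig:
    """Sampling ranges for random augmentation.

    Defaults: rotation within +/-40 degrees, shifts within +/-5 px,
    shear within +/-0.2 rad, zoom in [0.8, 1.2], horizontal flip with
    probability 0.5 — a conventional setting for 50x50 patches; the
    ranges are fully configurable.
    """

    theta_range: tuple[float, float] = (-math.radians(40), math.radians(40))
    shift_range: tuple[float, float] = (-5.0, 5.0)
    shear_range: tuple[float, float] = (-0.2, 0.2)
    zoom_range: tuple[float, float] = (0.8, 1.2)
    flip_prob: float = 0.5
    interpolation: str = "bilinear"   # or "nearest"
    fill: str = "edge"                # or "constant:<value>"

    def __post_init__(self):
        for lo, hi in (self.theta_range, self.shift_range,
                       self.shear_range, self.zoom_range):
            if hi < lo:
                raise ValueError("ranges must be non-empty (lo <= hi)")
        if not 0 <= self.flip_prob <= 1:
            raise ValueError("flip_prob must lie in [0, 1]")
        if self.interpolation not in ("bilinear", "nearest"):
            raise ValueError(f"unknown interpolation {self.interpolation!r}")
        if not (self.fill == "edge" or self.fill.startswith("constant")):
            raise ValueError(f"unknown fill {self.fill!r}")


@dataclass
class PreprocSpec:
    """Pixel preprocessing: 'rescale_01' (x/255) or 'standardize'
    ((x - mean)/std with one global scalar mean/std)."""

    mode: str = "rescale_01"
    mean: float = 0.0
    std: float = 1.0

    def __post_init__(self):
        if self.mode not in ("rescale_01", "standardize"):
            raise ValueError(f"unknown preprocessing mode {self.mode!r}")
        if self.mode == "standardize" and self.std <= 0:
            raise ValueError("standardize requires std > 0")


# ---------------------------------------------------------------------------
# elementary transform matrices

def _center(h: int, w: int) -> tuple[float, float]:
    return (h + 1) / 2.0, (w + 1) / 2.0


def rotation_matrix(theta: float, h: int, w: int) -> np.ndarray:
    """Rotation by ``theta`` about the image center."""
    if not math.isfinite(theta):
        raise ValueError("theta must be finite")
    if h < 1 or w < 1:
        raise ValueError("image dimensions must be >= 1")
    ch, cw = _center(h, w)
    c, s = math.cos(theta), math.sin(theta)
    return np.array([
        [c, -s, -c * ch + s * cw + ch],
        [s, c, -s * ch - c * cw + cw],
        [0.0, 0.0, 1.0],
    ])


def shift_matrix(tx: float, ty: float) -> np.ndarray:
    """Translation by ``tx`` rows and ``ty`` columns."""
    if not (math.isfinite(tx) and math.isfinite(ty)):
        raise ValueError("shifts must be finite")
    return np.array([[1.0, 0.0, tx], [0.0, 1.0, ty], [0.0, 0.0, 1.0]])


def shear_matrix(shear: float, h: int, w: int) -> np.ndarray:
    """Shear of intensity ``shear`` with the image center fixed.

    Linear part ((1, -sin), (0, cos)); offsets are constructed to keep
    the center invariant.
    """
    if not math.isfinite(shear) or abs(shear) >= math.pi / 2:
        raise ValueError("|shear| must be < pi/2")
    ch, cw = _center(h, w)
    s, c = math.sin(shear), math.cos(shear)
    return np.array([
        [1.0, -s, s * cw],
        [0.0, c, -c * cw + cw],
        [0.0, 0.0, 1.0],
    ])


def zoom_matrix(zx: float, zy: float, h: int, w: int) -> np.ndarray:
    """Anisotropic zoom about the image center."""
    if zx <= 0 or zy <= 0:
        raise ValueError("zoom factors must be positive")
    ch, cw = _center(h, w)
    return np.array([
        [zx, 0.0, -zx * ch + ch],
        [0.0, zy, -zy * cw + cw],
        [0.0, 0.0, 1.0],
    ])


def compose(params: AffineParams, h: int, w: int) -> np.ndarray:
    """Rotation @ shift @ shear @ zoom (flip handled separately)."""
    return (rotation_matrix(params.theta, h, w)
            @ shift_matrix(params.tx, params.ty)
            @ shear_matrix(params.shear, h, w)
            @ zoom_matrix(params.zx, params.zy, h, w))


# ---------------------------------------------------------------------------
# resampling

def apply_transform(image: np.ndarray, m: np.ndarray,
                    config: AugmentConfig | None = None) -> np.ndarray:
    """Resample ``image`` under the homogeneous matrix ``m``.

    The matrix maps output to input coordinates in the 1-based (row,
    col) convention; scipy's 0-based pull resampling is used with the
    offset adjusted accordingly.  Output is clipped to [0, 255] uint8.
    """
    config = config or AugmentConfig()
    m = np.asarray(m, dtype=float)
    if m.shape != (3, 3):
        raise ValueError("transform matrix must be 3x3")
    lin, off = m[:2, :2], m[:2, 2]
    if abs(np.linalg.det(lin)) < 1e-12:
        raise ValueError("singular transform matrix")
    # 1-based -> 0-based: in0 = lin @ (out0 + 1) + off - 1
    offset0 = lin @ np.ones(2) + off - np.ones(2)
    order = 1 if config.interpolation == "bilinear" else 0
    if config.fill == "edge":
        mode, cval = "nearest", 0.0
    else:
        mode = "constant"
        _, _, val = config.fill.partition(":")
        cval = float(val) if val else 0.0
    src = image.astype(np.float64)
    out = np.empty_like(src)
    for ch in range(image.shape[2]):
        out[:, :, ch] = ndimage.affine_transform(
            src[:, :, ch], lin, offset=offset0, order=order,
            mode=mode, cval=cval)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def hflip(image: np.ndarray) -> np.ndarray:
    return image[:, ::-1].copy()


def sample_params(config: AugmentConfig, rng: np.random.Generator) -> AffineParams:
    return AffineParams(
        theta=rng.uniform(*config.theta_range),
        tx=rng.uniform(*config.shift_range),
        ty=rng.uniform(*config.shift_range),
        shear=rng.uniform(*config.shear_range),
        zx=rng.uniform(*config.zoom_range),
        zy=rng.uniform(*config.zoom_range),
        flip=rng.random() < config.flip_prob,
    )


def random_augment(image: np.ndarray, config: AugmentConfig,
                   rng: np.random.Generator) -> np.ndarray:
    """One random draw: composed affine then horizontal flip."""
    p = sample_params(config, rng)
    h, w = image.shape[:2]
    out = apply_transform(image, compose(p, h, w), config)
    return hflip(out) if p.flip else out


def augment_to_target(pset: PatchSet, target_per_class: int,
                      config: AugmentConfig, seed: int) -> PatchSet:
    """Pad every class to ``target_per_class`` patches.

    Originals are retained unchanged and come first within each class;
    extras are augmented copies of the originals taken round-robin.
    Classes already at or above the target are left as they are.
    """
    rng = np.random.default_rng(seed)
    pixels, labels = [], []
    for ci in range(len(pset.class_names)):
        idx = np.flatnonzero(pset.labels == ci)
        if len(idx) == 0:
            raise ValueError(f"class {pset.class_names[ci]!r} is empty")
        pixels.append(pset.pixels[idx])
        labels.extend([ci] * len(idx))
        for j in range(max(0, target_per_class - len(idx))):
            src = pset.pixels[idx[j % len(idx)]]
            pixels.append(random_augment(src, config, rng)[None])
            labels.append(ci)
    return PatchSet(np.concatenate(pixels, axis=0),
                    np.asarray(labels), pset.class_names)


# ---------------------------------------------------------------------------
# preprocessing

def preprocess(image: np.ndarray, spec: PreprocSpec) -> np.ndarray:
    """Map raw 0-255 pixels to model inputs (float32)."""
    x = np.asarray(image, dtype=np.float32)
    if spec.mode == "rescale_01":
        return x / np.float32(255.0)
    return (x - np.float32(spec.mean)) / np.float32(spec.std)


def fit_standardizer(pixels: np.ndarray) -> PreprocSpec:
    """Global scalar mean/std over all pixels and channels of a
    (training) array, as used for the seven-class task."""
    x = np.asarray(pixels, dtype=np.float64)
    return PreprocSpec(mode="standardize", mean=float(x.mean()),
                       std=float(x.std()))


__all__ = [
    "AffineParams", "AugmentConfig", "PreprocSpec",
    "rotation_matrix", "shift_matrix", "shear_matrix", "zoom_matrix",
    "compose", "apply_transform", "hflip", "sample_params",
    "random_augment", "augment_to_target", "preprocess", "fit_standardizer",
]
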