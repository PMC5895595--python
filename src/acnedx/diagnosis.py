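"""Whole-face diagnosis: tile, mask, classify, aggregate, report.

A face image is cut into abutting 50x50 tiles by a stride-50 sliding
window.  The binary classifier flags each tile skin or non-skin at its
operating threshold; non-skin tiles are blacked out.  The seven-class
classifier labels every skin tile, and the per-class fractions of
those argmax decisions form the integral report.  The symptom set is
derived from the fractions by the reconstructed rule: ignore normal
skin (c3), keep classes whose fraction clears a threshold (default
0.10), cap the selection at the three largest (boundary ties resolved
toward the lower class index).
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .models import TrainedClassifier
from .synthetic import PATCH_SIZE
from .vocab import NORMAL_SKIN, SEVEN_CLASSES

SYMPTOM_THRESHOLD = 0.10
SYMPTOM_CAP = 3


@dataclass
class TileGrid:
    tiles: np.ndarray     # (rows*cols, 50, 50, 3) uint8, row-major
    rows: int
    cols: int
    origins: np.ndarray   # (rows*cols, 2) top-left (row, col) pixel offsets
    pad_mask: np.ndarray  # (rows, cols) bool, True where the tile is padding


@dataclass
class SkinMask:
    flags: np.ndarray             # (rows, cols) bool, True = skin
    skin_probability: np.ndarray  # (rows, cols) float


@dataclass
class DiagnosisReport:
    proportions: np.ndarray       # 7-vector over c0..c6, sums to 1 if skin found
    symptom_set: tuple[int, ...]  # class indices, ascending; never contains c3
    n_skin_tiles: int
    n_masked_tiles: int
    mask: SkinMask
    tile_labels: dict[tuple[int, int], int] = field(default_factory=dict)
    valid: bool = True            # False when no skin tile was found


def tile(image: np.ndarray, tile_size: int = PATCH_SIZE) -> TileGrid:
    """Non-overlapping stride-``tile_size`` tiling, row-major.

    Images whose sides are not multiples of the tile size are padded
    bottom/right with black; padded tiles are flagged and later forced
    non-skin.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    h, w = image.shape[:2]
    ph, pw = (-h) % tile_size, (-w) % tile_size
    if ph or pw:
        warnings.warn(f"image {h}x{w} is not a multiple of {tile_size}; "
                      "padding bottom/right with black", stacklevel=2)
        image = np.pad(image, ((0, ph), (0, pw), (0, 0)))
    rows = image.shape[0] // tile_size
    cols = image.shape[1] // tile_size
    tiles = (image.reshape(rows, tile_size, cols, tile_size, 3)
             .swapaxes(1, 2).reshape(rows * cols, tile_size, tile_size, 3))
    origins = np.array([(r * tile_size, c * tile_size)
                        for r in range(rows) for c in range(cols)])
    pad_mask = np.zeros((rows, cols), dtype=bool)
    if ph:
        pad_mask[-1, :] |= (rows * tile_size > h)
    if pw:
        pad_mask[:, -1] |= (cols * tile_size > w)
    return TileGrid(np.ascontiguousarray(tiles), rows, cols, origins, pad_mask)


def detect_skin(grid: TileGrid, binary: TrainedClassifier,
                threshold: float | None = None) -> SkinMask:
    """Flag tiles whose skin-class probability reaches the operating
    threshold (the classifier's stored Youden-optimal threshold unless
    overridden)."""
    if threshold is None:
        threshold = binary.decision_threshold
        if threshold is None:
            threshold = 0.5
    skin_col = binary.class_names.index("skin")
    probs = binary.predict_proba(grid.tiles)[:, skin_col]
    probs = probs.reshape(grid.rows, grid.cols)
    flags = probs >= threshold
    flags[grid.pad_mask] = False
    return SkinMask(flags=flags, skin_probability=probs)


def mask_image(image: np.ndarray, mask: SkinMask,
               tile_size: int = PATCH_SIZE) -> np.ndarray:
    """Black out non-skin tiles; skin tiles pass through untouched."""
    rows, cols = mask.flags.shape
    if image.shape[:2] != (rows * tile_size, cols * tile_size):
        raise ValueError("mask shape does not match image")
    out = image.copy()
    for r in range(rows):
        for c in range(cols):
            if not mask.flags[r, c]:
                out[r * tile_size:(r + 1) * tile_size,
                    c * tile_size:(c + 1) * tile_size] = 0
    return out


def classify_tiles(grid: TileGrid, mask: SkinMask,
                   seven: TrainedClassifier):
    """Seven-class probabilities and argmax labels for skin tiles only.

    Returns ``(indices, probs, labels)`` where ``indices`` are flat
    row-major tile positions of the skin-flagged tiles.
    """
    flat = mask.flags.ravel()
    indices = np.flatnonzero(flat)
    if len(indices) == 0:
        return indices, np.zeros((0, 7)), np.zeros(0, dtype=int)
    probs = seven.predict_proba(grid.tiles[indices])
    return indices, probs, probs.argmax(axis=1)


def proportions(tile_labels: np.ndarray, k: int = 7) -> np.ndarray:
    """Fraction of skin tiles whose argmax decision is each class."""
    tile_labels = np.asarray(tile_labels)
    if len(tile_labels) == 0:
        raise ValueError("proportions are undefined with zero skin tiles")
    return np.bincount(tile_labels, minlength=k) / len(tile_labels)


def determine_symptoms(p, threshold: float = SYMPTOM_THRESHOLD,
                       cap: int = SYMPTOM_CAP) -> tuple[int, ...]:
    """Symptom set from a 7-vector of class proportions.

    Normal skin (c3) is ignored; classes with proportion >= threshold
    qualify; if more than ``cap`` qualify, the ``cap`` largest are
    kept, ties resolved toward the lower class index.  Returned in
    ascending class order.
    """
    p = np.asarray(p, dtype=float)
    if p.shape != (7,):
        raise ValueError("expected a 7-vector of proportions")
    candidates = [c for c in range(7)
                  if c != NORMAL_SKIN and p[c] >= threshold]
    candidates.sort(key=lambda c: (-p[c], c))
    return tuple(sorted(candidates[:cap]))


def diagnose(image: np.ndarray, binary: TrainedClassifier,
             seven: TrainedClassifier, skin_threshold: float | None = None,
             symptom_threshold: float = SYMPTOM_THRESHOLD,
             symptom_cap: int = SYMPTOM_CAP) -> DiagnosisReport:
    """End-to-end diagnosis of one face image."""
    grid = tile(image)
    mask = detect_skin(grid, binary, threshold=skin_threshold)
    indices, _, labels = classify_tiles(grid, mask, seven)
    n_skin = len(indices)
    n_masked = grid.rows * grid.cols - n_skin
    if n_skin == 0:
        return DiagnosisReport(
            proportions=np.zeros(7), symptom_set=(), n_skin_tiles=0,
            n_masked_tiles=n_masked, mask=mask, valid=False)
    props = proportions(labels)
    tile_map = {(int(i // grid.cols), int(i % grid.cols)): int(l)
                for i, l in zip(indices, labels)}
    return DiagnosisReport(
        proportions=props,
        symptom_set=determine_symptoms(props, symptom_threshold, symptom_cap),
        n_skin_tiles=n_skin, n_masked_tiles=n_masked, mask=mask,
        tile_labels=tile_map)


# ---------------------------------------------------------------------------
# report writers

def report_to_json(report: DiagnosisReport, path: str | Path) -> None:
    payload = {
        "proportions": {f"c{i}": round(float(v), 2)
                        for i, v in enumerate(report.proportions)},
        "class_names": list(SEVEN_CLASSES),
        "symptom_set": [f"c{c}" for c in report.symptom_set],
        "n_skin_tiles": report.n_skin_tiles,
        "n_masked_tiles": report.n_masked_tiles,
        "valid": report.valid,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def write_mask_png(image: np.ndarray, mask: SkinMask,
                   path: str | Path) -> None:
    Image.fromarray(mask_image(image, mask)).save(path)


def tiles_to_csv(report: DiagnosisReport, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["row", "col", "skin_prob", "is_skin", "argmax_class"])
        rows, cols = report.mask.flags.shape
        for r in range(rows):
            for c in range(cols):
                label = report.tile_labels.get((r, c))
                w.writerow([r, c,
                            f"{report.mask.skin_probability[r, c]:.4f}",
                            int(report.mask.flags[r, c]),
                            "" if label is None else f"c{label}"])


__all__ = [
    "TileGrid", "SkinMask", "DiagnosisReport",
    "tile", "detect_skin", "mask_image", "classify_tiles",
    "proportions", "determine_symptoms", "diagnose",
    "report_to_json", "write_mask_png", "tiles_to_csv",
    "SYMPTOM_THRESHOLD", "SYMPTOM_CAP",
]
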