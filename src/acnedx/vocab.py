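"""Class vocabularies shared across the pipeline.

Seven-class ids follow the lesion coding c0..c6: papule (c0), cyst (c1),
blackhead (c2), normal skin (c3), pustule (c4), whitehead (c5),
nodule (c6).  The binary task codes skin as class 0 (the positive class)
and non-skin as class 1.
"""

from __future__ import annotations

SEVEN_CLASSES: tuple[str, ...] = (
    "papule", "cyst", "blackhead", "normal", "pustule", "whitehead", "nodule",
)
BINARY_CLASSES: tuple[str, ...] = ("skin", "non_skin")

NORMAL_SKIN = 3          # c3
NON_SKIN = 7             # tile-truth code for non-skin in face fixtures
FACE_CLASSES: tuple[str, ...] = SEVEN_CLASSES + ("non_skin",)

_ALIASES = {f"c{i}": name for i, name in enumerate(SEVEN_CLASSES)}
_ALIASES["skin"] = "normal"  # the skin recipe is lesion-free normal skin


def canonical_class(class_id: str | int, vocab: tuple[str, ...]) -> int:
    """Map a class name, c-alias, or index into ``vocab``; raise on unknown."""
    if isinstance(class_id, (int,)) and not isinstance(class_id, bool):
        if 0 <= class_id < len(vocab):
            return int(class_id)
        raise ValueError(f"class index {class_id} outside vocabulary "
                         f"of size {len(vocab)}")
    name = str(class_id)
    if name in vocab:
        return vocab.index(name)
    if name in _ALIASES and _ALIASES[name] in vocab:
        return vocab.index(_ALIASES[name])
    raise ValueError(f"unknown class {class_id!r} for vocabulary {vocab}")
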