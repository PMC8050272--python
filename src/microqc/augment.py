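"""Deterministic D4 augmentation for paired images and bounding boxes.

The eight symmetries of the square (identity, three 90-degree rotations, the
two axis flips and the two diagonal reflections) multiply a paired dataset by
exactly 8; the rotation-only and flip-only subgroups give factors 4 and 3+1.
Bounding boxes are mapped by the exact coordinate transform of each symmetry
on the half-open pixel grid, so a transformed box always covers exactly the
transformed pixels of the original box.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from .detection import BoundingBox, DetectionSet

__all__ = [
    "D4_NAMES",
    "ROTATION_NAMES",
    "FLIP_NAMES",
    "apply_transform",
    "inverse_name",
    "d4_augment_pair",
    "transform_boxes",
]

D4_NAMES = (
    "identity",
    "rot90",
    "rot180",
    "rot270",
    "flip_h",
    "flip_v",
    "transpose",
    "anti_transpose",
)
ROTATION_NAMES = ("identity", "rot90", "rot180", "rot270")
FLIP_NAMES = ("identity", "flip_h", "flip_v")

_ARRAY_OPS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "identity": lambda a: a.copy(),
    "rot90": lambda a: np.rot90(a, 1).copy(),
    "rot180": lambda a: np.rot90(a, 2).copy(),
    "rot270": lambda a: np.rot90(a, 3).copy(),
    "flip_h": lambda a: a[:, ::-1].copy(),
    "flip_v": lambda a: a[::-1, :].copy(),
    "transpose": lambda a: a.swapaxes(0, 1).copy(),
    "anti_transpose": lambda a: a.swapaxes(0, 1)[::-1, ::-1].copy(),
}

_INVERSES = {
    "identity": "identity",
    "rot90": "rot270",
    "rot180": "rot180",
    "rot270": "rot90",
    "flip_h": "flip_h",
    "flip_v": "flip_v",
    "transpose": "transpose",
    "anti_transpose": "anti_transpose",
}


def apply_transform(image: np.ndarray, name: str) -> np.ndarray:
    """Apply one named D4 symmetry to a 2D raster."""
    if name not in _ARRAY_OPS:
        raise ValueError(f"unknown transform {name!r}; choose from {D4_NAMES}")
    return _ARRAY_OPS[name](np.asarray(image))


def inverse_name(name: str) -> str:
    """Name of the inverse element of a D4 symmetry."""
    return _INVERSES[name]


def d4_augment_pair(
    source: np.ndarray,
    target: np.ndarray,
    names: tuple[str, ...] = D4_NAMES,
) -> list[tuple[np.ndarray, np.ndarray, str]]:
    """All transforms of a source/target pair (identity included), same
    symmetry applied to both members, in deterministic order."""
    source = np.asarray(source)
    target = np.asarray(target)
    if source.shape != target.shape:
        raise ValueError(f"shape mismatch: {source.shape} vs {target.shape}")
    return [(apply_transform(source, n), apply_transform(target, n), n) for n in names]


def _map_point(x: float, y: float, w: int, h: int, name: str) -> tuple[float, float]:
    # Continuous coordinates on the half-open [0, w) x [0, h) grid.
    if name == "identity":
        return x, y
    if name == "flip_h":
        return w - x, y
    if name == "flip_v":
        return x, h - y
    if name == "rot180":
        return w - x, h - y
    if name == "rot90":  # counter-clockwise; output frame is h' = w, w' = h
        return y, w - x
    if name == "rot270":
        return h - y, x
    if name == "transpose":
        return y, x
    if name == "anti_transpose":
        return h - y, w - x
    raise ValueError(f"unknown transform {name!r}")


def transform_boxes(
    image: np.ndarray, detections: DetectionSet, name: str
) -> tuple[np.ndarray, DetectionSet]:
    """Transform an image and its bounding boxes by the same D4 symmetry.

    Box corners are mapped exactly and re-normalised so xmin < xmax and
    ymin < ymax; class names and confidences are preserved.
    """
    image = np.asarray(image)
    h, w = image.shape[:2]
    out_boxes = []
    for b in detections.boxes:
        if b.xmin < 0 or b.ymin < 0 or b.xmax > w or b.ymax > h:
            raise ValueError(f"box {b} exceeds the {h}x{w} image bounds")
        x0, y0 = _map_point(b.xmin, b.ymin, w, h, name)
        x1, y1 = _map_point(b.xmax, b.ymax, w, h, name)
        out_boxes.append(
            BoundingBox(
                b.class_name,
                min(x0, x1),
                min(y0, y1),
                max(x0, x1),
                max(y0, y1),
                b.confidence,
            )
        )
    return (
        apply_transform(image, name),
        DetectionSet(image_name=f"{detections.image_name}_{name}", boxes=out_boxes),
    )
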