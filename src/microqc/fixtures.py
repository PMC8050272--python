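"""Deterministic synthetic scenes for exercising every QC module.

These generators emulate, at desk scale, the data types the QC metrics are
meant for: fluorescently labelled nuclei with exact instance ground truth,
noisy/clean restoration pairs with a Poisson + Gaussian camera model, and
object-detection scenes whose prediction sets carry a known, countable amount
of corruption so expected precision/recall are computable in closed form.
Every generator is a pure function of its spec, seed included.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .detection import BoundingBox, DetectionSet

__all__ = [
    "SceneSpec",
    "make_nuclei_scene",
    "make_noisy_pair",
    "make_detection_scene",
    "make_drift_scene",
]


@dataclass
class SceneSpec:
    """Parameters of a synthetic scene."""

    image_shape: tuple[int, int] = (128, 128)
    n_objects: int = 10
    object_size_range: tuple[int, int] = (6, 12)
    classes: tuple[str, ...] = ("round", "elongated")
    gaussian_sigma: float = 0.05
    poisson_scale: float = 100.0
    seed: int = 0


def make_nuclei_scene(spec: SceneSpec) -> tuple[np.ndarray, np.ndarray]:
    """Non-overlapping elliptical "nuclei" with exact label ground truth.

    Returns (label image, fluorescence raster).  Objects are placed by
    rejection sampling; an infeasible packing raises after bounded attempts.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_shape
    labels = np.zeros((h, w), dtype=np.int32)
    rr, cc = np.mgrid[0:h, 0:w]
    placed = 0
    for attempt in range(spec.n_objects * 200):
        if placed == spec.n_objects:
            break
        a = rng.uniform(*spec.object_size_range) / 2
        b = rng.uniform(*spec.object_size_range) / 2
        theta = rng.uniform(0, np.pi)
        cy = rng.uniform(a + 1, h - a - 1)
        cx = rng.uniform(a + 1, w - a - 1)
        ct, st = np.cos(theta), np.sin(theta)
        u = (cc - cx) * ct + (rr - cy) * st
        v = -(cc - cx) * st + (rr - cy) * ct
        mask = (u / a) ** 2 + (v / b) ** 2 <= 1
        if not mask.any() or (labels[mask] != 0).any():
            continue
        placed += 1
        labels[mask] = placed
    if placed < spec.n_objects:
        raise RuntimeError(
            f"could not pack {spec.n_objects} objects of size {spec.object_size_range} "
            f"into {spec.image_shape}"
        )
    intensities = rng.uniform(0.5, 1.0, spec.n_objects + 1)
    intensities[0] = 0.0
    fluor = ndimage.gaussian_filter(intensities[labels], sigma=1.0) + 0.05
    return labels, fluor.astype(np.float64)


def make_noisy_pair(
    clean: np.ndarray,
    gaussian_sigma: float = 0.05,
    poisson_scale: float = 100.0,
    seed: int = 0,
) -> np.ndarray:
    """Shot + read noise: ``Poisson(clean * scale)/scale + N(0, sigma)``."""
    clean = np.asarray(clean, dtype=np.float64)
    if (clean < 0).any():
        raise ValueError("clean image must be non-negative")
    rng = np.random.default_rng(seed)
    noisy = rng.poisson(clean * poisson_scale) / poisson_scale
    return noisy + rng.normal(0.0, gaussian_sigma, clean.shape)


@dataclass
class DetectionScene:
    image: np.ndarray
    ground_truth: DetectionSet
    prediction: DetectionSet
    drop_fraction: float = 0.0
    false_positive_count: int = 0


def make_detection_scene(
    spec: SceneSpec,
    corruption: float = 0.0,
    jitter_px: float = 1.0,
    image_name: str = "scene",
) -> DetectionScene:
    """Textured blobs with GT boxes and a controllably corrupted prediction set.

    A ``corruption`` fraction of ground-truth boxes is dropped and replaced by
    random false positives; the surviving predictions are lightly jittered and
    assigned higher confidences than the false positives, so at the full
    ranking recall = 1 - corruption exactly (per rounding of the drop count).
    """
    if not 0 <= corruption <= 1:
        raise ValueError("corruption must lie in [0, 1]")
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_shape
    image = rng.normal(0.1, 0.02, (h, w))
    gt_boxes: list[BoundingBox] = []
    lo, hi = spec.object_size_range
    for k in range(spec.n_objects):
        cls = spec.classes[k % len(spec.classes)]
        bw = rng.integers(lo, hi + 1)
        bh = bw if cls == "round" else int(bw * rng.uniform(1.8, 2.5))
        bh = min(bh, h - 2)
        x0 = int(rng.integers(0, w - bw))
        y0 = int(rng.integers(0, h - bh))
        image[y0 : y0 + bh, x0 : x0 + bw] += rng.uniform(0.5, 1.0)
        gt_boxes.append(BoundingBox(cls, x0, y0, x0 + bw, y0 + bh))
    n_drop = int(round(corruption * len(gt_boxes)))
    dropped = set(rng.choice(len(gt_boxes), size=n_drop, replace=False)) if n_drop else set()
    pred_boxes: list[BoundingBox] = []
    for i, b in enumerate(gt_boxes):
        if i in dropped:
            continue
        dx, dy = rng.uniform(-jitter_px, jitter_px, 2)
        x0 = float(np.clip(b.xmin + dx, 0, w - 2))
        y0 = float(np.clip(b.ymin + dy, 0, h - 2))
        pred_boxes.append(
            BoundingBox(
                b.class_name,
                x0,
                y0,
                min(x0 + (b.xmax - b.xmin), w),
                min(y0 + (b.ymax - b.ymin), h),
                confidence=float(rng.uniform(0.7, 1.0)),
            )
        )
    for _ in range(n_drop):  # false positives, lower confidence than every TP
        bw = int(rng.integers(lo, hi + 1))
        bh = int(rng.integers(lo, hi + 1))
        x0 = int(rng.integers(0, w - bw))
        y0 = int(rng.integers(0, h - bh))
        cls = spec.classes[int(rng.integers(0, len(spec.classes)))]
        pred_boxes.append(
            BoundingBox(cls, x0, y0, x0 + bw, y0 + bh, confidence=float(rng.uniform(0.1, 0.4)))
        )
    return DetectionScene(
        image=image,
        ground_truth=DetectionSet(image_name, gt_boxes),
        prediction=DetectionSet(image_name, pred_boxes),
        drop_fraction=n_drop / max(1, len(gt_boxes)),
        false_positive_count=n_drop,
    )


def make_drift_scene(
    n_sites: int = 40,
    n_frames: int = 200,
    fov_nm: float = 5000.0,
    drift_per_frame_nm: tuple[float, float] = (0.5, 0.25),
    jitter_nm: float = 5.0,
    sites_per_frame: int = 15,
    seed: int = 0,
):
    """Blinking binding sites with linear stage drift, for drift-recovery tests.

    Returns (LocalisationTable, true DriftTrace).  Sites are fixed structured
    positions; each frame a random subset blinks on with small localisation
    jitter, displaced by the accumulated drift.
    """
    from .smlm import DriftTrace
    from .core_io import LocalisationTable

    rng = np.random.default_rng(seed)
    sx = rng.uniform(0.1 * fov_nm, 0.9 * fov_nm, n_sites)
    sy = rng.uniform(0.1 * fov_nm, 0.9 * fov_nm, n_sites)
    frames, xs, ys = [], [], []
    for f in range(1, n_frames + 1):
        dx = drift_per_frame_nm[0] * (f - 1)
        dy = drift_per_frame_nm[1] * (f - 1)
        on = rng.choice(n_sites, size=min(sites_per_frame, n_sites), replace=False)
        for s in on:
            frames.append(f)
            xs.append(sx[s] + dx + rng.normal(0, jitter_nm))
            ys.append(sy[s] + dy + rng.normal(0, jitter_nm))
    table = LocalisationTable.from_arrays(frames, xs, ys)
    f_idx = np.arange(n_frames, dtype=float)
    trace = DriftTrace(drift_per_frame_nm[0] * f_idx, drift_per_frame_nm[1] * f_idx)
    return table, trace
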