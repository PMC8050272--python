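"""Object-detection quality control for YOLO-style outputs.

Bounding boxes use 0-based, half-open pixel coordinates internally; Pascal VOC
XML (1-based, inclusive) is converted on read and write.  Evaluation follows
the standard confidence-ranked protocol: per class, predictions are sorted by
descending confidence and greedily matched (best IoU first) to unused
ground-truth boxes at IoU >= tau; the precision-recall curve over that ranking
yields AP (all-point interpolation by default, PASCAL VOC 11-point optionally),
and mAP is the unweighted mean over classes present in the ground truth.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "BoundingBox",
    "DetectionSet",
    "PRCurve",
    "box_iou",
    "match_detections",
    "pr_curve",
    "map_score",
    "detection_f1",
    "evaluate_detections",
    "read_voc_xml",
    "write_voc_xml",
]


@dataclass(frozen=True)
class BoundingBox:
    """A class-labelled box; coordinates 0-based half-open, optional confidence."""

    class_name: str
    xmin: float
    ymin: float
    xmax: float
    ymax: float
    confidence: float | None = None

    def __post_init__(self) -> None:
        if not (self.xmax > self.xmin and self.ymax > self.ymin):
            raise ValueError(
                f"degenerate box ({self.xmin},{self.ymin},{self.xmax},{self.ymax})"
            )

    @property
    def area(self) -> float:
        return (self.xmax - self.xmin) * (self.ymax - self.ymin)


@dataclass
class DetectionSet:
    """All boxes for one image."""

    image_name: str
    boxes: list[BoundingBox] = field(default_factory=list)


@dataclass
class PRCurve:
    """Precision-recall curve along a confidence ranking, with its AP."""

    recall: np.ndarray
    precision: np.ndarray
    ap: float
    class_name: str = ""
    flagged: bool = False


@dataclass
class RankedMatch:
    """One ranked prediction with its TP/FP label."""

    image_name: str
    confidence: float
    is_tp: bool
    iou: float


def box_iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two boxes; 0 when disjoint."""
    ix = min(a.xmax, b.xmax) - max(a.xmin, b.xmin)
    iy = min(a.ymax, b.ymax) - max(a.ymin, b.ymin)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def _rank_key(image_name: str, box: BoundingBox) -> tuple:
    # Stable tie-break on equal confidence: by image name, then coordinates.
    return (-box.confidence, image_name, box.xmin, box.ymin, box.xmax, box.ymax)


def match_detections(
    gt: list[DetectionSet],
    pred: list[DetectionSet],
    tau: float = 0.5,
) -> tuple[dict[str, list[RankedMatch]], dict[str, int]]:
    """Confidence-ranked TP/FP labelling per class.

    Returns (ranked matches per class, ground-truth box count per class).
    Each prediction is a TP if it overlaps (IoU >= tau) a not-yet-matched
    same-class ground-truth box in the same image, taking the best-IoU one;
    otherwise it is an FP.
    """
    if not 0 < tau < 1:
        raise ValueError("tau must lie strictly between 0 and 1")
    gt_by_image: dict[str, list[BoundingBox]] = {s.image_name: list(s.boxes) for s in gt}
    n_gt: dict[str, int] = {}
    for s in gt:
        for b in s.boxes:
            n_gt[b.class_name] = n_gt.get(b.class_name, 0) + 1

    ranked: list[tuple[tuple, str, BoundingBox]] = []
    for s in pred:
        for b in s.boxes:
            if b.confidence is None:
                raise ValueError(f"prediction without confidence in image {s.image_name!r}")
            ranked.append((_rank_key(s.image_name, b), s.image_name, b))
    ranked.sort(key=lambda t: t[0])

    used: set[tuple[str, int]] = set()  # (image, index into gt list) already matched
    per_class: dict[str, list[RankedMatch]] = {c: [] for c in n_gt}
    for _, image_name, b in ranked:
        candidates = gt_by_image.get(image_name, [])
        best_iou, best_idx = 0.0, -1
        for idx, g in enumerate(candidates):
            if g.class_name != b.class_name or (image_name, idx) in used:
                continue
            iou = box_iou(b, g)
            if iou > best_iou:
                best_iou, best_idx = iou, idx
        is_tp = best_iou >= tau and best_idx >= 0
        if is_tp:
            used.add((image_name, best_idx))
        per_class.setdefault(b.class_name, []).append(
            RankedMatch(image_name, b.confidence, is_tp, best_iou if is_tp else 0.0)
        )
    return per_class, n_gt


def pr_curve(
    matches: list[RankedMatch], n_gt: int, interpolation: str = "all_point", class_name: str = ""
) -> PRCurve:
    """Precision-recall curve and AP for one class's ranked matches.

    ``all_point``: the precision envelope is made non-increasing from the right
    and integrated over recall.  ``voc11``: mean of the envelope sampled at the
    11 recalls 0, 0.1, ..., 1.
    """
    if n_gt == 0:
        return PRCurve(np.zeros(0), np.zeros(0), 0.0, class_name, flagged=True)
    tp = np.array([m.is_tp for m in matches], dtype=float)
    cum_tp = np.cumsum(tp)
    ranks = np.arange(1, len(matches) + 1)
    recall = cum_tp / n_gt
    precision = cum_tp / ranks
    # envelope with virtual endpoints at recall 0 and final recall
    r = np.concatenate([[0.0], recall])
    p = np.concatenate([[1.0], precision])
    env = np.maximum.accumulate(p[::-1])[::-1]
    if interpolation == "all_point":
        ap = float(np.sum((r[1:] - r[:-1]) * env[1:]))
    elif interpolation == "voc11":
        ap = float(np.mean([env[r >= t].max() if (r >= t).any() else 0.0 for t in np.linspace(0, 1, 11)]))
    else:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    return PRCurve(recall, precision, ap, class_name)


def map_score(curves: list[PRCurve]) -> float:
    """Unweighted mean AP over the given per-class curves."""
    if not curves:
        raise ValueError("mAP needs at least one class")
    return float(np.mean([c.ap for c in curves]))


def detection_f1(
    matches_by_class: dict[str, list[RankedMatch]],
    n_gt: dict[str, int],
    confidence: float = 0.3,
) -> float:
    """F1 over all classes at the operating confidence threshold.

    Predictions below ``confidence`` are discarded; FN = ground-truth boxes not
    matched by a kept TP.
    """
    tp = fp = 0
    total_gt = sum(n_gt.values())
    for cls, matches in matches_by_class.items():
        for m in matches:
            if m.confidence >= confidence:
                tp += m.is_tp
                fp += not m.is_tp
    fn = total_gt - tp
    if 2 * tp + fp + fn == 0:
        return 0.0
    return 2 * tp / (2 * tp + fp + fn)


def evaluate_detections(
    gt: list[DetectionSet],
    pred: list[DetectionSet],
    tau: float = 0.5,
    confidence: float = 0.3,
    interpolation: str = "all_point",
) -> dict:
    """One-call detection QC: per-class PR curves + AP, mAP, F1."""
    per_class, n_gt = match_detections(gt, pred, tau)
    curves = [
        pr_curve(per_class.get(cls, []), n, interpolation, cls) for cls, n in sorted(n_gt.items())
    ]
    return {
        "curves": curves,
        "ap": {c.class_name: c.ap for c in curves},
        "map": map_score(curves) if curves else 0.0,
        "f1": detection_f1(per_class, n_gt, confidence),
        "tau": tau,
        "confidence": confidence,
        "interpolation": interpolation,
    }


# ---------------------------------------------------------------------------
# Pascal VOC XML


def read_voc_xml(path: str | Path) -> DetectionSet:
    """Read Pascal VOC XML annotations (1-based inclusive -> half-open)."""
    path = Path(path)
    root = ET.parse(path).getroot()
    name_el = root.find("filename")
    image_name = name_el.text if name_el is not None and name_el.text else path.stem
    boxes = []
    for obj in root.iter("object"):
        cls = obj.findtext("name", default="object")
        bb = obj.find("bndbox")
        if bb is None:
            continue
        xmin = float(bb.findtext("xmin")) - 1
        ymin = float(bb.findtext("ymin")) - 1
        xmax = float(bb.findtext("xmax"))
        ymax = float(bb.findtext("ymax"))
        conf_text = obj.findtext("confidence")
        conf = float(conf_text) if conf_text is not None else None
        boxes.append(BoundingBox(cls, xmin, ymin, xmax, ymax, conf))
    return DetectionSet(image_name=image_name, boxes=boxes)


def write_voc_xml(
    detections: DetectionSet,
    path: str | Path,
    image_shape: tuple[int, int] | None = None,
) -> None:
    """Write a detection set as Pascal VOC XML (half-open -> 1-based inclusive)."""
    root = ET.Element("annotation")
    ET.SubElement(root, "filename").text = detections.image_name
    if image_shape is not None:
        size = ET.SubElement(root, "size")
        ET.SubElement(size, "height").text = str(image_shape[0])
        ET.SubElement(size, "width").text = str(image_shape[1])
        ET.SubElement(size, "depth").text = "1"
    for b in detections.boxes:
        obj = ET.SubElement(root, "object")
        ET.SubElement(obj, "name").text = b.class_name
        if b.confidence is not None:
            ET.SubElement(obj, "confidence").text = repr(b.confidence)
        bb = ET.SubElement(obj, "bndbox")
        ET.SubElement(bb, "xmin").text = repr(b.xmin + 1)
        ET.SubElement(bb, "ymin").text = repr(b.ymin + 1)
        ET.SubElement(bb, "xmax").text = repr(b.xmax)
        ET.SubElement(bb, "ymax").text = repr(b.ymax)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ET.ElementTree(root).write(path, encoding="unicode", xml_declaration=True)
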