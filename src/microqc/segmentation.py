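"""Semantic and instance segmentation quality control.

Semantic masks are scored by intersection-over-union (IoU), with an automatic
sweep to find the binarisation threshold that maximises IoU against ground
truth.  Instance label images are scored by one-to-one matching of ground-truth
and predicted objects at an IoU threshold tau, from which precision, recall,
F1, mean matched IoU (segmentation quality, SQ), recognition quality (RQ) and
Panoptic Quality (PQ = SQ * RQ) follow.  Per-object IoU maps localise failures
visually, and instance centroids can be exported as TrackMate-ready tracking
input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .core_io import ImageStack, LocalisationTable

__all__ = [
    "MatchConfig",
    "MatchResult",
    "InstanceScores",
    "semantic_iou",
    "optimize_threshold",
    "label_iou_matrix",
    "match_instances",
    "instance_scores",
    "instance_iou_map",
    "export_centroids",
]


@dataclass
class MatchConfig:
    """Instance-matching configuration: IoU acceptance threshold and strategy."""

    tau: float = 0.5
    strategy: str = "hungarian"  # or "greedy"

    def __post_init__(self) -> None:
        if not 0 < self.tau < 1:
            raise ValueError("tau must lie strictly between 0 and 1")
        if self.strategy not in ("hungarian", "greedy"):
            raise ValueError(f"unknown matching strategy {self.strategy!r}")


@dataclass
class MatchResult:
    """One-to-one instance matches plus TP/FP/FN counts."""

    matches: list[tuple[int, int, float]]  # (gt_label, pred_label, iou)
    tp: int
    fp: int
    fn: int
    tau: float

    @property
    def matched_ious(self) -> np.ndarray:
        return np.array([iou for _, _, iou in self.matches])


@dataclass
class InstanceScores:
    precision: float
    recall: float
    f1: float
    mean_matched_iou: float  # SQ
    rq: float
    pq: float
    flagged: bool = False

    def as_dict(self) -> dict[str, float]:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "mean_matched_iou": self.mean_matched_iou,
            "rq": self.rq,
            "pq": self.pq,
        }


def semantic_iou(a: np.ndarray, b: np.ndarray) -> float:
    """IoU of two binary masks: |a AND b| / |a OR b|; 1 when both are empty."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0  # both empty; flagged convention to avoid NaN in batch QC
    return float(np.logical_and(a, b).sum() / union)


def optimize_threshold(
    probability: np.ndarray, gt: np.ndarray
) -> tuple[int, float, list[tuple[int, float]]]:
    """Sweep 8-bit thresholds 1..254 and return the IoU-maximising one.

    Float maps are min-max rescaled to 8-bit first; binarisation is
    ``rescaled >= threshold``.  Ties go to the lowest threshold; a constant map
    returns threshold 127 with the (degenerate) IoU of an all-ones mask.
    """
    probability = np.asarray(probability)
    gt = np.asarray(gt).astype(bool)
    if probability.shape != gt.shape:
        raise ValueError("probability map and ground truth must share one shape")
    p = probability.astype(np.float64)
    lo, hi = p.min(), p.max()
    if hi == lo:
        return 127, semantic_iou(np.ones_like(gt), gt), []
    scaled = np.round((p - lo) / (hi - lo) * 255.0)
    curve = [(t, semantic_iou(scaled >= t, gt)) for t in range(1, 255)]
    ious = np.array([iou for _, iou in curve])
    best_idx = int(np.argmax(ious))  # argmax takes the first (lowest) on ties
    return curve[best_idx][0], curve[best_idx][1], curve


def label_iou_matrix(
    gt: np.ndarray, pred: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pairwise IoU between every ground-truth and predicted instance.

    Returns (gt_labels, pred_labels, iou matrix of shape (n_gt, n_pred)).
    Computed from the joint label histogram, so cost is one pass over pixels.
    """
    gt = np.asarray(gt).astype(np.int64)
    pred = np.asarray(pred).astype(np.int64)
    if gt.shape != pred.shape:
        raise ValueError(f"shape mismatch: {gt.shape} vs {pred.shape}")
    gt_labels = np.unique(gt[gt > 0])
    pred_labels = np.unique(pred[pred > 0])
    if len(gt_labels) == 0 or len(pred_labels) == 0:
        return gt_labels, pred_labels, np.zeros((len(gt_labels), len(pred_labels)))
    gt_idx = np.searchsorted(gt_labels, gt.ravel())
    pred_idx = np.searchsorted(pred_labels, pred.ravel())
    fg = (gt.ravel() > 0) & (pred.ravel() > 0)
    inter = np.zeros((len(gt_labels), len(pred_labels)), dtype=np.int64)
    np.add.at(inter, (gt_idx[fg], pred_idx[fg]), 1)
    gt_area = np.array([(gt == lab).sum() for lab in gt_labels])
    pred_area = np.array([(pred == lab).sum() for lab in pred_labels])
    union = gt_area[:, None] + pred_area[None, :] - inter
    return gt_labels, pred_labels, inter / union


def match_instances(
    gt: np.ndarray, pred: np.ndarray, cfg: MatchConfig | None = None
) -> MatchResult:
    """One-to-one matching of instances with IoU >= tau.

    Default strategy is the optimal assignment maximising total IoU
    (Hungarian) over eligible pairs; ``greedy`` picks pairs in descending IoU
    order instead.
    """
    cfg = cfg or MatchConfig()
    gt_labels, pred_labels, iou = label_iou_matrix(gt, pred)
    matches: list[tuple[int, int, float]] = []
    if iou.size:
        if cfg.strategy == "hungarian":
            eligible = np.where(iou >= cfg.tau, iou, 0.0)
            rows, cols = linear_sum_assignment(-eligible)
            for r, c in zip(rows, cols):
                if iou[r, c] >= cfg.tau:
                    matches.append((int(gt_labels[r]), int(pred_labels[c]), float(iou[r, c])))
        else:
            order = np.argsort(iou, axis=None)[::-1]
            used_r: set[int] = set()
            used_c: set[int] = set()
            for flat in order:
                r, c = np.unravel_index(flat, iou.shape)
                if iou[r, c] < cfg.tau:
                    break
                if r not in used_r and c not in used_c:
                    used_r.add(int(r))
                    used_c.add(int(c))
                    matches.append((int(gt_labels[r]), int(pred_labels[c]), float(iou[r, c])))
    tp = len(matches)
    return MatchResult(
        matches=matches,
        tp=tp,
        fp=len(pred_labels) - tp,
        fn=len(gt_labels) - tp,
        tau=cfg.tau,
    )


def instance_scores(match: MatchResult) -> InstanceScores:
    """Precision, recall, F1, SQ, RQ and PQ from a match result.

    With no true positives all scores are 0 and the result is flagged.
    """
    tp, fp, fn = match.tp, match.fp, match.fn
    if tp == 0:
        return InstanceScores(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, flagged=True)
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    f1 = 2 * tp / (2 * tp + fp + fn)
    sq = float(match.matched_ious.mean())
    rq = tp / (tp + fp / 2 + fn / 2)
    return InstanceScores(precision, recall, f1, sq, rq, sq * rq)


def instance_iou_map(gt: np.ndarray, pred: np.ndarray, match: MatchResult) -> np.ndarray:
    """Paint every predicted instance with its matched IoU (0 if unmatched)."""
    pred = np.asarray(pred).astype(np.int64)
    out = np.zeros(pred.shape, dtype=np.float32)
    iou_by_pred = {p: iou for _, p, iou in match.matches}
    for lab in np.unique(pred[pred > 0]):
        out[pred == lab] = iou_by_pred.get(int(lab), 0.0)
    return out


def export_centroids(
    labels: list[np.ndarray] | np.ndarray, pixel_size_nm: float | None = None
) -> tuple[LocalisationTable, ImageStack]:
    """Per-frame instance centroids as a tracking table plus a dot stack.

    Centroids are the pixel-centre means of each instance (x = mean col + 0.5,
    in pixels, scaled to nm when a pixel size is given).  The companion stack
    marks each rounded centroid with a single white pixel on black, ready for
    TrackMate-style spot import.
    """
    label_list = [np.asarray(lab).astype(np.int64) for lab in labels]
    px = pixel_size_nm if pixel_size_nm is not None else 1.0
    frames, xs, ys = [], [], []
    dots = np.zeros((len(label_list),) + label_list[0].shape, dtype=np.uint8)
    for k, lab in enumerate(label_list):
        for instance in np.unique(lab[lab > 0]):
            rows, cols = np.nonzero(lab == instance)
            cy, cx = rows.mean(), cols.mean()
            frames.append(k + 1)
            xs.append((cx + 0.5) * px)
            ys.append((cy + 0.5) * px)
            dots[k, int(round(cy)), int(round(cx))] = 255
    table = LocalisationTable.from_arrays(frames, xs, ys)
    return table, ImageStack(frames=dots, pixel_size_nm=pixel_size_nm)
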