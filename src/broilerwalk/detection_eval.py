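"""Evaluation of bird/keypoint detections against reference annotations.

Implements the standard single-class object-detection metrics used to
benchmark a walkway bird detector: IoU, greedy confidence-descending
matching, 101-point interpolated average precision (AP), mAP50 and
mAP50-95 (mean AP over IoU thresholds 0.50:0.05:0.95), precision/recall/F1,
and a distance-threshold evaluation for the head keypoint.

Detection records travel as CSV with columns
``bird_id,frame,conf,x_min,y_min,x_max,y_max,head_x,head_y`` (pixels,
0-based frames, origin top-left, y downward); annotations use the same
schema without ``conf``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

DETECTION_COLUMNS = [
    "bird_id", "frame", "conf",
    "x_min", "y_min", "x_max", "y_max",
    "head_x", "head_y",
]
ANNOTATION_COLUMNS = [c for c in DETECTION_COLUMNS if c != "conf"]

#: IoU thresholds over which mAP50-95 averages.
MAP_THRESHOLDS = np.round(np.arange(0.50, 0.96, 0.05), 2)

#: Recall grid of the 101-point interpolated AP.
RECALL_GRID = np.linspace(0.0, 1.0, 101)


@dataclass
class EvalResult:
    """Detection-evaluation summary at a reference IoU threshold.

    ``ap_per_threshold`` maps each IoU threshold in ``MAP_THRESHOLDS`` to
    its AP; ``pr_curve`` holds (recall, precision) points of the raw
    curve at the reference threshold (0.5).
    """

    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    ap_per_threshold: dict[float, float]
    map50: float
    map50_95: float
    pr_curve: list[tuple[float, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn,
            "precision": self.precision, "recall": self.recall, "f1": self.f1,
            "ap_per_threshold": {f"{k:.2f}": v for k, v in self.ap_per_threshold.items()},
            "mAP50": self.map50, "mAP50_95": self.map50_95,
            "pr_curve": self.pr_curve,
        }


# ---------------------------------------------------------------------------
# Box geometry
# ---------------------------------------------------------------------------

def iou(box_a: Sequence[float], box_b: Sequence[float]) -> float:
    """Intersection-over-union of two ``(x_min, y_min, x_max, y_max)`` boxes.

    Raises ``ValueError`` on degenerate (zero-area) boxes; returns 0.0 for
    disjoint boxes.
    """
    ax0, ay0, ax1, ay1 = box_a
    bx0, by0, bx1, by1 = box_b
    area_a = (ax1 - ax0) * (ay1 - ay0)
    area_b = (bx1 - bx0) * (by1 - by0)
    if area_a <= 0 or area_b <= 0:
        raise ValueError("degenerate box with non-positive area")
    iw = min(ax1, bx1) - max(ax0, bx0)
    ih = min(ay1, by1) - max(ay0, by0)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    return inter / (area_a + area_b - inter)


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------

def match_detections(
    preds: pd.DataFrame,
    truths: pd.DataFrame,
    iou_threshold: float = 0.5,
) -> tuple[int, int, int, np.ndarray]:
    """Greedy per-frame matching of predictions to ground-truth boxes.

    Predictions are visited in descending confidence; each truth box may be
    claimed at most once, by the prediction with the highest IoU among the
    still-unmatched truths of the same frame. A prediction is a true
    positive iff that IoU reaches ``iou_threshold``.

    Returns ``(TP, FP, FN, flags)`` where ``flags`` is a boolean array over
    predictions in descending-confidence order (True = TP). Empty inputs
    are allowed.
    """
    preds = preds.sort_values("conf", ascending=False, kind="mergesort").reset_index(drop=True)
    n_truths = len(truths)
    flags = np.zeros(len(preds), dtype=bool)
    matched: set[tuple[int, int]] = set()  # (frame, row index within frame)
    truth_by_frame: dict[int, pd.DataFrame] = {
        int(f): g.reset_index(drop=True) for f, g in truths.groupby("frame")
    } if n_truths else {}
    for i, p in preds.iterrows():
        frame = int(p["frame"])
        cand = truth_by_frame.get(frame)
        if cand is None:
            continue
        best_j, best_iou = -1, 0.0
        pbox = (p["x_min"], p["y_min"], p["x_max"], p["y_max"])
        for j, t in cand.iterrows():
            if (frame, j) in matched:
                continue
            v = iou(pbox, (t["x_min"], t["y_min"], t["x_max"], t["y_max"]))
            if v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0 and best_iou >= iou_threshold:
            matched.add((frame, best_j))
            flags[i] = True
    tp = int(flags.sum())
    fp = len(preds) - tp
    fn = n_truths - tp
    return tp, fp, fn, flags


# ---------------------------------------------------------------------------
# Precision / recall / AP
# ---------------------------------------------------------------------------

def precision_recall(tp: int, fp: int, fn: int) -> tuple[float, float]:
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    return precision, recall


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 (with a warning) if both are 0."""
    if not (0 <= precision <= 1 and 0 <= recall <= 1):
        raise ValueError("precision and recall must lie in [0, 1]")
    if precision == 0 and recall == 0:
        import warnings

        warnings.warn("precision and recall both zero; F1 defined as 0")
        return 0.0
    return 2 * precision * recall / (precision + recall)


def pr_curve_points(flags: np.ndarray, n_truths: int) -> tuple[np.ndarray, np.ndarray]:
    """Raw cumulative (recall, precision) points, detections already ranked."""
    tp_cum = np.cumsum(flags)
    fp_cum = np.cumsum(~flags.astype(bool))
    ranks = np.arange(1, len(flags) + 1)
    precision = tp_cum / ranks
    recall = tp_cum / n_truths if n_truths > 0 else np.zeros_like(precision)
    return recall, precision


def average_precision(flags: np.ndarray, n_truths: int) -> float:
    """101-point interpolated AP from ranked TP/FP flags.

    The precision envelope (running max of precision from the right) is
    sampled at recalls 0.00, 0.01, ..., 1.00 and averaged. With no truths
    and no predictions AP is undefined and a ``ValueError`` is raised.
    """
    flags = np.asarray(flags, dtype=bool)
    if n_truths == 0 and len(flags) == 0:
        raise ValueError("AP undefined: no ground truths and no predictions")
    if n_truths == 0:
        return 0.0
    if len(flags) == 0:
        return 0.0
    recall, precision = pr_curve_points(flags, n_truths)
    # Envelope: precision at recall r is max precision at any recall >= r.
    env = np.maximum.accumulate(precision[::-1])[::-1]
    sampled = np.zeros_like(RECALL_GRID)
    for i, r in enumerate(RECALL_GRID):
        mask = recall >= r - 1e-12
        sampled[i] = env[mask][0] if mask.any() else 0.0
    return float(sampled.mean())


def evaluate_detections(
    preds: pd.DataFrame,
    truths: pd.DataFrame,
    reference_threshold: float = 0.5,
) -> EvalResult:
    """Full box-detection evaluation: counts and F1 at the reference IoU
    threshold, AP per threshold, mAP50 and mAP50-95."""
    ap: dict[float, float] = {}
    for thr in MAP_THRESHOLDS:
        tp, fp, fn, flags = match_detections(preds, truths, float(thr))
        ap[float(thr)] = average_precision(flags, len(truths))
    tp, fp, fn, flags = match_detections(preds, truths, reference_threshold)
    precision, recall = precision_recall(tp, fp, fn)
    rec, prec = pr_curve_points(flags, len(truths)) if len(preds) else (np.array([]), np.array([]))
    return EvalResult(
        tp=tp, fp=fp, fn=fn,
        precision=precision, recall=recall,
        f1=f1_score(precision, recall) if (precision or recall) else 0.0,
        ap_per_threshold=ap,
        map50=ap[0.5],
        map50_95=float(np.mean(list(ap.values()))),
        pr_curve=list(zip(rec.tolist(), prec.tolist())),
    )


# ---------------------------------------------------------------------------
# Keypoints
# ---------------------------------------------------------------------------

def evaluate_keypoints(
    preds: pd.DataFrame,
    truths: pd.DataFrame,
    tolerance: float = 0.1,
    iou_threshold: float = 0.5,
) -> EvalResult:
    """Head-keypoint evaluation on box-matched detections.

    A predicted keypoint is correct iff it lies within
    ``tolerance * truth-box diagonal`` of the reference keypoint; the
    correctness flags then feed the same precision/recall/AP machinery as
    boxes. Truth rows must carry ``head_x``/``head_y``.
    """
    if truths[["head_x", "head_y"]].isna().any().any():
        raise ValueError("missing keypoints in ground-truth annotations")
    preds = preds.sort_values("conf", ascending=False, kind="mergesort").reset_index(drop=True)
    ap: dict[float, float] = {}
    ref_flags = None
    for thr in MAP_THRESHOLDS:
        flags = _keypoint_flags(preds, truths, tolerance, float(thr))
        ap[float(thr)] = average_precision(flags, len(truths))
        if abs(thr - iou_threshold) < 1e-9:
            ref_flags = flags
    if ref_flags is None:
        ref_flags = _keypoint_flags(preds, truths, tolerance, iou_threshold)
    tp = int(ref_flags.sum())
    fp = len(preds) - tp
    fn = len(truths) - tp
    precision, recall = precision_recall(tp, fp, fn)
    rec, prec = pr_curve_points(ref_flags, len(truths)) if len(preds) else (np.array([]), np.array([]))
    return EvalResult(
        tp=tp, fp=fp, fn=fn, precision=precision, recall=recall,
        f1=f1_score(precision, recall) if (precision or recall) else 0.0,
        ap_per_threshold=ap, map50=ap[0.5],
        map50_95=float(np.mean(list(ap.values()))),
        pr_curve=list(zip(rec.tolist(), prec.tolist())),
    )


def _keypoint_flags(preds, truths, tolerance, iou_threshold) -> np.ndarray:
    """TP flags for keypoints: box-matched AND within the scaled radius."""
    flags = np.zeros(len(preds), dtype=bool)
    matched: set[tuple[int, int]] = set()
    truth_by_frame = {int(f): g.reset_index(drop=True) for f, g in truths.groupby("frame")}
    for i, p in preds.iterrows():
        frame = int(p["frame"])
        cand = truth_by_frame.get(frame)
        if cand is None:
            continue
        best_j, best_iou = -1, 0.0
        pbox = (p["x_min"], p["y_min"], p["x_max"], p["y_max"])
        for j, t in cand.iterrows():
            if (frame, j) in matched:
                continue
            v = iou(pbox, (t["x_min"], t["y_min"], t["x_max"], t["y_max"]))
            if v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0 and best_iou >= iou_threshold:
            matched.add((frame, best_j))
            t = cand.loc[best_j]
            diag = float(np.hypot(t["x_max"] - t["x_min"], t["y_max"] - t["y_min"]))
            dist = float(np.hypot(p["head_x"] - t["head_x"], p["head_y"] - t["head_y"]))
            flags[i] = dist <= tolerance * diag
    return flags


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_detections(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(DETECTION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"detection CSV missing columns: {sorted(missing)}")
    return df


def read_annotations(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation CSV missing columns: {sorted(missing)}")
    return df


def write_detections(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_eval_result(result: EvalResult, json_path, pr_csv_path=None) -> None:
    with open(json_path, "w") as fh:
        json.dump(result.to_dict(), fh, indent=2)
    if pr_csv_path is not None:
        pd.DataFrame(result.pr_curve, columns=["recall", "precision"]).to_csv(
            pr_csv_path, index=False
        )
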