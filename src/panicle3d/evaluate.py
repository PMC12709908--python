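"""Detection metrics and panicle morphometrics.

Average precision / recall of oriented-box detections under greedy
score-descending matching, per-point segmentation accuracy, and the
box-derived panicle size metrics (length, width, height, radius) used to
compare varieties.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .geometry import LEAF, PANICLE, STEM, OrientedBox, box_iou_3d

__all__ = [
    "average_precision",
    "segmentation_accuracy",
    "panicle_morphometrics",
    "summarize_plot",
]

_CLASS_NAMES = {PANICLE: "panicle", STEM: "stem", LEAF: "leaf"}


def average_precision(
    pred_boxes: list[OrientedBox],
    scores: np.ndarray,
    gt_boxes: list[OrientedBox],
    iou_threshold: float,
) -> tuple[float, float]:
    """AP and AR of a detection set against ground truth at one IoU threshold.

    Predictions are visited in descending score order (ties by index); each
    claims the unmatched ground-truth box of highest IoU provided it reaches
    the threshold.  AP integrates the precision envelope over all score cut
    points (the all-point interpolation); AR is the matched fraction of
    ground truth using every prediction.

    Empty ground truth with empty predictions scores AP = 1 by convention
    (nothing to find, nothing hallucinated); empty predictions against
    non-empty ground truth score 0.
    """
    scores = np.asarray(scores, dtype=float).reshape(-1)
    n_pred, n_gt = len(pred_boxes), len(gt_boxes)
    if n_pred == 0:
        return (1.0, 1.0) if n_gt == 0 else (0.0, 0.0)
    if n_gt == 0:
        return 0.0, 1.0
    order = np.argsort(-scores, kind="stable")
    matched = np.zeros(n_gt, dtype=bool)
    tp = np.zeros(n_pred)
    for rank, pi in enumerate(order):
        ious = np.array(
            [
                0.0 if matched[gi] else box_iou_3d(pred_boxes[int(pi)], gt_boxes[gi])
                for gi in range(n_gt)
            ]
        )
        best = int(np.argmax(ious))
        if ious[best] >= iou_threshold:
            matched[best] = True
            tp[rank] = 1.0
    cum_tp = np.cumsum(tp)
    recall = cum_tp / n_gt
    precision = cum_tp / np.arange(1, n_pred + 1)
    # precision envelope: best precision at any recall >= r
    env = np.maximum.accumulate(precision[::-1])[::-1]
    r = np.concatenate([[0.0], recall])
    ap = float(np.sum((r[1:] - r[:-1]) * env))
    ar = float(matched.mean())
    return ap, ar


def segmentation_accuracy(
    pred_labels: np.ndarray, true_labels: np.ndarray, mode: str = "all-class"
) -> float:
    """Per-point segmentation accuracy.

    ``"all-class"`` is the unweighted mean of per-class recalls over
    panicle/stem/leaf (a class absent from the truth is excluded with a
    warning); ``"panicle-only"`` is the recall of the panicle class alone,
    the mode used when only panicle labels exist.
    """
    pred = np.asarray(pred_labels).reshape(-1)
    true = np.asarray(true_labels).reshape(-1)
    if pred.shape != true.shape:
        raise ValueError("label arrays must align")
    if mode == "panicle-only":
        mask = true == PANICLE
        if not mask.any():
            raise ValueError("no panicle points in the ground truth")
        return float((pred[mask] == PANICLE).mean())
    if mode != "all-class":
        raise ValueError(f"unknown mode {mode!r}")
    recalls = []
    for c, name in _CLASS_NAMES.items():
        mask = true == c
        if not mask.any():
            warnings.warn(f"class {name!r} absent from ground truth; excluded")
            continue
        recalls.append(float((pred[mask] == c).mean()))
    if not recalls:
        raise ValueError("no known classes present in the ground truth")
    return float(np.mean(recalls))


def panicle_morphometrics(boxes: list[OrientedBox]) -> pd.DataFrame:
    """Panicle size metrics from detection boxes.

    Height is the vertical (z) extent; length and width are the larger and
    smaller horizontal extents; radius summarises the horizontal footprint
    as ``(length + width) / 4`` — the mean horizontal semi-axis.  All in
    metres, one row per detection.
    """
    rows = []
    for b in boxes:
        if np.any(b.dims <= 0):
            raise ValueError(f"box dims must be positive, got {b.dims}")
        length = float(max(b.dims[0], b.dims[1]))
        width = float(min(b.dims[0], b.dims[1]))
        rows.append(
            {
                "height_m": float(b.dims[2]),
                "length_m": length,
                "width_m": width,
                "radius_m": (length + width) / 4.0,
            }
        )
    return pd.DataFrame(rows, columns=["height_m", "length_m", "width_m", "radius_m"])


def summarize_plot(boxes: list[OrientedBox], bins: int = 12) -> dict:
    """Per-plot summary: count, means, and histograms of radius and height."""
    df = panicle_morphometrics(boxes)
    out = {"count": int(len(df))}
    for col in df.columns:
        if len(df):
            counts, edges = np.histogram(df[col], bins=bins)
            out[col] = {
                "mean": float(df[col].mean()),
                "std": float(df[col].std(ddof=0)),
                "hist_counts": counts.tolist(),
                "hist_edges": edges.tolist(),
            }
    return out
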