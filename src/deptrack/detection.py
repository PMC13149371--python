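"""Cell detection states, a reference blob detector, and detection scoring.

The tracker consumes per-frame centroid-radius detection states
``d = (x, y, r)``, with the radius derived from a bounding box as
``r = (w + h) / 4``.  Any callable producing such states can be plugged in —
including a CSV stream exported by an external neural detector.  The
bundled reference backend is a multiscale Laplacian-of-Gaussian blob
detector suited to the synthetic renderer's bright cell discs.

Scoring follows the usual set-based counts: one-to-one matching of
predictions to ground truth within a centroid-distance tolerance yields
TP/FP/FN, from which precision, recall and the F-measure are computed and
reported to five decimals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from skimage.feature import blob_log

from deptrack.fovmask import FoVMask, contains_many

__all__ = [
    "Detection",
    "DetectionMetrics",
    "bbox_to_state",
    "blob_detect",
    "detections_from_dataframe",
    "match_to_ground_truth",
    "detection_metrics",
]


@dataclass(frozen=True)
class Detection:
    """Centroid-radius detection state of one cell in one frame."""

    frame: int
    x: float
    y: float
    r: float
    w: float = 0.0
    h: float = 0.0
    score: float = 1.0

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError("detection radius must be positive")

    @property
    def xy(self) -> tuple[float, float]:
        return (self.x, self.y)


def bbox_to_state(
    x: float, y: float, w: float, h: float, frame: int = 0, score: float = 1.0
) -> Detection:
    """Convert a centroid + bounding box to a detection state, r = (w + h)/4."""
    if w <= 0 or h <= 0:
        raise ValueError("bounding box sides must be positive")
    return Detection(frame=frame, x=x, y=y, r=(w + h) / 4.0, w=w, h=h, score=score)


def detections_from_dataframe(df: pd.DataFrame) -> dict[int, list[Detection]]:
    """Group a detection-stream DataFrame (frame, x, y, w, h[, score]) by frame."""
    out: dict[int, list[Detection]] = {}
    has_score = "score" in df.columns
    for row in df.itertuples(index=False):
        det = bbox_to_state(
            row.x,
            row.y,
            row.w,
            row.h,
            frame=int(row.frame),
            score=float(row.score) if has_score else 1.0,
        )
        out.setdefault(det.frame, []).append(det)
    return out


def blob_detect(
    frame: np.ndarray,
    mask: FoVMask | None = None,
    min_r: float = 3.0,
    max_r: float = 10.0,
    threshold: float = 0.2,
    frame_index: int = 0,
) -> list[Detection]:
    """Reference detector: multiscale LoG blob maxima of bright discs.

    Detections whose centroid falls outside ``mask`` are dropped.  The blob
    radius is recovered from the responding scale (r = sqrt(2) * sigma).
    Deterministic for fixed inputs; an empty list is a valid result.
    """
    if min_r >= max_r:
        raise ValueError("min_r must be < max_r")
    img = np.asarray(frame, dtype=float) / 255.0
    blobs = blob_log(
        img,
        min_sigma=min_r / np.sqrt(2),
        max_sigma=max_r / np.sqrt(2),
        num_sigma=14,
        threshold=threshold,
        overlap=0.3,
    )
    dets = []
    for row_y, col_x, sigma in blobs:
        r = float(sigma * np.sqrt(2))
        dets.append(
            Detection(
                frame=frame_index,
                x=float(col_x),
                y=float(row_y),
                r=r,
                w=2 * r,
                h=2 * r,
                score=1.0,
            )
        )
    if mask is not None and dets:
        pts = np.array([[d.x, d.y] for d in dets])
        keep = contains_many(mask, pts)
        dets = [d for d, k in zip(dets, keep) if k]
    dets.sort(key=lambda d: (d.y, d.x))
    return dets


def match_to_ground_truth(
    pred: list[Detection] | np.ndarray,
    gt: list | np.ndarray,
    tol: float,
) -> tuple[int, int, int]:
    """Optimal one-to-one matching of predictions to ground truth.

    The TP count is the cardinality of the maximum bipartite matching over
    pairs within centroid distance ``tol`` (solved as a linear assignment
    with prohibitive cost on out-of-tolerance pairs; among maximum
    matchings, total distance is minimal).  Returns ``(tp, fp, fn)`` with
    ``tp + fp == len(pred)`` and ``tp + fn == len(gt)``.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    p = np.array([[d.x, d.y] if isinstance(d, Detection) else d[:2] for d in pred],
                 dtype=float).reshape(-1, 2)
    g = np.array([[d.x, d.y] if isinstance(d, Detection) else d[:2] for d in gt],
                 dtype=float).reshape(-1, 2)
    if len(p) == 0 or len(g) == 0:
        return 0, len(p), len(g)
    dist = np.hypot(p[:, 0:1] - g[None, :, 0], p[:, 1:2] - g[None, :, 1])
    big = tol * (len(p) + len(g) + 1) + 1.0
    cost = np.where(dist <= tol, dist, big)
    rows, cols = linear_sum_assignment(cost)
    tp = int(np.count_nonzero(dist[rows, cols] <= tol))
    return tp, len(p) - tp, len(g) - tp


@dataclass(frozen=True)
class DetectionMetrics:
    """Precision / recall / F-measure, reported to five decimals."""

    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f_measure: float


def detection_metrics(tp: int, fp: int, fn: int) -> DetectionMetrics:
    """Exact ratio metrics from TP/FP/FN counts, rounded to 5 decimals.

    Raises ``ValueError`` when a denominator is zero (metrics undefined).
    """
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    if tp + fp == 0 or tp + fn == 0:
        raise ValueError("metrics not computable: zero denominator")
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    f = 2 * precision * recall / (precision + recall)
    return DetectionMetrics(
        tp=tp,
        fp=fp,
        fn=fn,
        precision=round(precision, 5),
        recall=round(recall, 5),
        f_measure=round(f, 5),
    )
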