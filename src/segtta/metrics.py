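"""Evaluation metrics: per-image mAP over IoU thresholds and pixel-level IoU.

``dsb_map`` implements the Kaggle Data Science Bowl 2018 scoring variant:
predictions and ground truth objects are matched one-to-one by IoU, and
the per-threshold score TP/(TP+FP+FN) is averaged over thresholds
0.50, 0.55, ..., 0.95.  The TP criterion is strict (IoU *greater than*
the threshold).

``compare`` pairs original (no TTA) and merged (with TTA) scores per
image, reports delta = merged - original, and runs a two-sided Wilcoxon
signed-rank test across images.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .instances import InstanceSet

__all__ = [
    "DEFAULT_THRESHOLDS",
    "EvalRecord",
    "ComparisonResult",
    "iou_table",
    "dsb_map",
    "dataset_map",
    "pixel_iou",
    "compare",
]

#: IoU thresholds 0.50 .. 0.95 in steps of 0.05.
DEFAULT_THRESHOLDS: tuple[float, ...] = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))


@dataclass(frozen=True)
class EvalRecord:
    """Per-image scores for the merged and original predictions."""

    image_id: str
    original_score: float
    merged_score: float

    @property
    def delta(self) -> float:
        return self.merged_score - self.original_score


@dataclass(frozen=True)
class ComparisonResult:
    records: list[EvalRecord]
    mean_delta: float
    median_delta: float
    p_value: Optional[float]
    degenerate: bool = False


def iou_table(pred: InstanceSet, gt: InstanceSet) -> np.ndarray:
    """Pairwise IoU matrix, shape (len(pred), len(gt)).

    Computed from the joint label histogram rather than per-pair mask
    comparisons; requires only that masks live on the same canvas.
    """
    if pred.shape != gt.shape:
        raise ValueError(f"canvas shapes differ: pred {pred.shape} vs gt {gt.shape}")
    n_p, n_g = len(pred), len(gt)
    table = np.zeros((n_p, n_g), dtype=np.float64)
    if n_p == 0 or n_g == 0:
        return table
    areas_p = np.array([m.sum() for m in pred.masks], dtype=np.int64)
    areas_g = np.array([m.sum() for m in gt.masks], dtype=np.int64)
    for i, pm in enumerate(pred.masks):
        for j, gm in enumerate(gt.masks):
            inter = np.count_nonzero(pm & gm)
            if inter:
                table[i, j] = inter / (areas_p[i] + areas_g[j] - inter)
    return table


def _greedy_pairs(table: np.ndarray) -> list[tuple[int, int, float]]:
    """One-to-one matching in descending IoU order (ties: lower indices)."""
    n_p, n_g = table.shape
    entries = [
        (table[i, j], i, j) for i in range(n_p) for j in range(n_g) if table[i, j] > 0
    ]
    entries.sort(key=lambda e: (-e[0], e[1], e[2]))
    used_p: set[int] = set()
    used_g: set[int] = set()
    pairs = []
    for iou, i, j in entries:
        if i in used_p or j in used_g:
            continue
        used_p.add(i)
        used_g.add(j)
        pairs.append((i, j, iou))
    return pairs


def dsb_map(
    pred: InstanceSet,
    gt: InstanceSet,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> float:
    """Mean of TP/(TP+FP+FN) over IoU thresholds for one image.

    Matching is one-to-one and computed once from the full IoU table in
    descending IoU order; at each threshold t, a matched pair counts as a
    true positive iff its IoU is strictly greater than t.  Unmatched
    predictions are false positives and unmatched ground-truth objects
    false negatives.

    Conventions for edge cases (never printed by the source metric, but
    needed for simulated scenes): both sets empty -> 1.0; exactly one
    empty -> 0.0.
    """
    if pred.shape != gt.shape:
        raise ValueError(f"canvas shapes differ: pred {pred.shape} vs gt {gt.shape}")
    if len(pred) == 0 and len(gt) == 0:
        return 1.0
    if len(pred) == 0 or len(gt) == 0:
        return 0.0
    pairs = _greedy_pairs(iou_table(pred, gt))
    ious = np.array([iou for _, _, iou in pairs], dtype=np.float64)
    n_p, n_g = len(pred), len(gt)
    total = 0.0
    for t in thresholds:
        tp = int((ious > t).sum())
        fp = n_p - tp
        fn = n_g - tp
        total += tp / (tp + fp + fn)
    return total / len(thresholds)


def dataset_map(scores: Sequence[float]) -> float:
    """Arithmetic mean of per-image scores; the final value is in [0, 1]."""
    if len(scores) == 0:
        raise ValueError("need at least one per-image score")
    return float(np.mean(scores))


def pixel_iou(pred: np.ndarray, gt: np.ndarray) -> float:
    """Pixel-level IoU of two binary masks via the sum-then-count procedure.

    The two masks are summed; pixels with value > 1 form the intersection
    and pixels with value > 0 the union.  Both masks empty -> 1.0 (a
    correct empty prediction is perfect).
    """
    pred = np.asarray(pred, dtype=bool)
    gt = np.asarray(gt, dtype=bool)
    if pred.shape != gt.shape:
        raise ValueError(f"mask shapes differ: {pred.shape} vs {gt.shape}")
    total = pred.astype(np.int64) + gt.astype(np.int64)
    union = int(np.count_nonzero(total > 0))
    if union == 0:
        return 1.0
    inter = int(np.count_nonzero(total > 1))
    return inter / union


def compare(
    original_scores: Sequence[float],
    merged_scores: Sequence[float],
    ids: Sequence[str] | None = None,
) -> ComparisonResult:
    """Pair per-image scores, compute deltas and a Wilcoxon signed-rank test.

    Fewer than two pairs, or all-zero deltas, make the test degenerate; the
    deltas are still reported, with ``p_value`` set to None.
    """
    if len(original_scores) != len(merged_scores):
        raise ValueError("original and merged score lists must have equal length")
    n = len(original_scores)
    if ids is None:
        ids = [str(i) for i in range(n)]
    elif len(ids) != n:
        raise ValueError("ids must match the number of score pairs")
    records = [
        EvalRecord(image_id=str(i), original_score=float(o), merged_score=float(m))
        for i, o, m in zip(ids, original_scores, merged_scores)
    ]
    deltas = np.array([r.delta for r in records], dtype=np.float64)
    mean_d = float(deltas.mean()) if n else math.nan
    median_d = float(np.median(deltas)) if n else math.nan
    p_value: Optional[float] = None
    degenerate = False
    if n < 2 or not np.any(deltas != 0):
        degenerate = True
    else:
        try:
            _, p = stats.wilcoxon(
                merged_scores, original_scores, alternative="two-sided"
            )
            p_value = float(p)
        except ValueError:
            degenerate = True
    return ComparisonResult(
        records=records,
        mean_delta=mean_d,
        median_delta=median_d,
        p_value=p_value,
        degenerate=degenerate,
    )
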