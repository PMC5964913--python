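"""Segmentation accuracy: overlap area, mean deviation distance, grading.

Overlap ``O = |pred & truth| / |truth| * 100`` measures how much of the
expert (ground-truth) area the automatic result covers. The mean deviation
distance ``Mad`` is the average, over the predicted contour points, of the
Euclidean distance to the nearest ground-truth contour point — directed, not
symmetrized, and reported in pixels. Slices are graded by overlap:
``accurate`` above 90%, ``fair`` in the inclusive 80-90% band, and
``unacceptable`` below 80%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .contour import mask_contours

__all__ = [
    "ACCURATE",
    "FAIR",
    "UNACCEPTABLE",
    "EvalReport",
    "overlap_area",
    "mean_deviation",
    "classify",
    "mask_contour_points",
    "evaluate_masks",
    "summarize",
]

ACCURATE = "accurate"
FAIR = "fair"
UNACCEPTABLE = "unacceptable"


@dataclass
class EvalReport:
    slice_index: int
    o: float          # overlap percentage
    mad: float        # mean deviation distance, pixels (nan if undefined)
    klass: str


def overlap_area(pred_mask: np.ndarray, truth_mask: np.ndarray) -> float:
    """Overlap percentage O of a predicted mask against a non-empty truth."""
    pred = np.asarray(pred_mask, dtype=bool)
    truth = np.asarray(truth_mask, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    denom = truth.sum()
    if denom == 0:
        raise ValueError("overlap is undefined for an empty truth mask")
    return float((pred & truth).sum() / denom * 100.0)


def mean_deviation(pred_contour: np.ndarray, truth_contour: np.ndarray) -> float:
    """Mean distance from each predicted contour point to the nearest
    ground-truth contour point (directed, in pixels)."""
    l1 = np.asarray(pred_contour, dtype=np.float64)
    l2 = np.asarray(truth_contour, dtype=np.float64)
    if l1.size == 0 or l2.size == 0:
        raise ValueError("contours must be non-empty")
    l1 = l1.reshape(-1, 2)
    l2 = l2.reshape(-1, 2)
    dists, _ = cKDTree(l2).query(l1)
    return float(np.mean(dists))


def classify(o: float) -> str:
    """Grade an overlap percentage (boundaries 80 and 90 fall in 'fair')."""
    if o < 0:
        raise ValueError("overlap percentage cannot be negative")
    if o > 90.0:
        return ACCURATE
    if o >= 80.0:
        return FAIR
    return UNACCEPTABLE


def mask_contour_points(mask: np.ndarray) -> np.ndarray:
    """All boundary points of a mask, concatenated over its components."""
    contours = mask_contours(mask)
    if not contours:
        raise ValueError("mask has no components to contour")
    return np.concatenate(contours, axis=0)


def evaluate_masks(
    pred_masks: np.ndarray,
    truth_masks: np.ndarray,
    slice_indices: list[int] | None = None,
) -> pd.DataFrame:
    """Per-slice overlap, deviation distance and grade as a DataFrame.

    Mad is NaN on slices where either mask has no contour (empty prediction).
    """
    pred_masks = np.asarray(pred_masks, dtype=bool)
    truth_masks = np.asarray(truth_masks, dtype=bool)
    if pred_masks.shape != truth_masks.shape:
        raise ValueError("prediction and truth stacks must share a shape")
    if slice_indices is None:
        slice_indices = list(range(1, len(pred_masks) + 1))
    rows = []
    for idx, pred, truth in zip(slice_indices, pred_masks, truth_masks):
        o = overlap_area(pred, truth)
        if pred.any() and truth.any():
            mad = mean_deviation(mask_contour_points(pred), mask_contour_points(truth))
        else:
            mad = float("nan")
        rows.append(
            {"slice": idx, "overlap_pct": o, "mad_px": mad, "class": classify(o)}
        )
    return pd.DataFrame(rows)


def summarize(report: pd.DataFrame) -> dict[str, float]:
    """Sequence-level summary: average overlap and per-class percentages."""
    n = len(report)
    counts = report["class"].value_counts()
    return {
        "average_overlap_pct": float(report["overlap_pct"].mean()),
        "accurate_pct": float(counts.get(ACCURATE, 0) / n * 100.0),
        "fair_pct": float(counts.get(FAIR, 0) / n * 100.0),
        "unacceptable_pct": float(counts.get(UNACCEPTABLE, 0) / n * 100.0),
        "mad_min_px": float(np.nanmin(report["mad_px"])) if n else float("nan"),
        "mad_max_px": float(np.nanmax(report["mad_px"])) if n else float("nan"),
    }
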