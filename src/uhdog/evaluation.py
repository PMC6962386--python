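"""Dot-based detection scoring.

Ground truth comes as dot annotations (blob centers). A candidate matches a
truth dot when their Euclidean distance is at most ``d``. True positives
are counted with duplicate protection,

    TP = min( #{j : min_i D_ij <= d}, #{i : min_j D_ij <= d} ),

i.e. the smaller of "candidates near some truth" and "truths near some
candidate" — not a one-to-one assignment. Precision = TP/n, recall = TP/m,
F-score is their harmonic mean.

The default matching radius is the average blob diameter derived from the
detected foreground: d = 2·sqrt(A/π) with A the average per-blob area (in
3D, the diameter of the average per-blob volume's equivalent sphere). The
literal variant, using the *total* foreground area, is switchable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .image_io import DotList
from .joint_detector import BlobSet

__all__ = [
    "DetectionMetrics",
    "default_distance_threshold",
    "count_true_positives",
    "compute_metrics",
    "evaluate_image",
    "summarize_batch",
]


@dataclass
class DetectionMetrics:
    """TP count and derived precision/recall/F for one image."""

    tp: int
    m: int  # ground-truth count
    n: int  # candidate count
    precision: float  # NaN when undefined (n == 0)
    recall: float  # NaN when undefined (m == 0)
    f_score: float
    d: float

    @property
    def precision_defined(self) -> bool:
        return not np.isnan(self.precision)

    @property
    def recall_defined(self) -> bool:
        return not np.isnan(self.recall)


def default_distance_threshold(
    mask, n_blobs: int, mode: str = "average"
) -> float:
    """Average-blob-diameter matching radius from a binary foreground map.

    ``mode="average"`` divides the foreground area by ``n_blobs`` before
    taking the equivalent-disc diameter; ``mode="literal"`` uses the total
    area (the diameter of the pooled foreground).
    """
    data = np.asarray(getattr(mask, "data", mask)).astype(bool)
    if n_blobs < 1:
        raise ValueError("n_blobs must be >= 1")
    area = float(data.sum())
    if area == 0:
        raise ValueError("foreground is empty; distance threshold undefined")
    if mode == "average":
        area /= n_blobs
    elif mode != "literal":
        raise ValueError(f"unknown mode {mode!r}")
    if data.ndim == 2:
        return 2.0 * float(np.sqrt(area / np.pi))
    return 2.0 * float((3.0 * area / (4.0 * np.pi)) ** (1.0 / 3.0))


def count_true_positives(truth: DotList, candidates: DotList, d: float) -> int:
    """Duplicate-protected TP count (see module docstring)."""
    if d <= 0:
        raise ValueError("matching threshold d must be > 0")
    m, n = truth.count, candidates.count
    if m == 0 or n == 0:
        return 0
    D = cdist(truth.points, candidates.points)
    matched_candidates = int((D.min(axis=0) <= d).sum())
    matched_truths = int((D.min(axis=1) <= d).sum())
    return min(matched_candidates, matched_truths)


def compute_metrics(tp: int, m: int, n: int, d: float) -> DetectionMetrics:
    """Precision/recall/F from a TP count; undefined ratios become NaN."""
    if tp > min(m, n):
        raise ValueError(f"tp={tp} exceeds min(m={m}, n={n})")
    precision = tp / n if n > 0 else float("nan")
    recall = tp / m if m > 0 else float("nan")
    p = 0.0 if np.isnan(precision) else precision
    r = 0.0 if np.isnan(recall) else recall
    f = 0.0 if (p + r) == 0 else 2.0 * p * r / (p + r)
    return DetectionMetrics(tp, m, n, precision, recall, f, d)


def evaluate_image(
    truth: DotList, blobs: BlobSet, d: float | None = None
) -> DetectionMetrics:
    """Score a detection against ground-truth dots.

    Candidates are the blob intensity centroids. When ``d`` is omitted it
    defaults to the average-diameter rule on the detected foreground.
    """
    candidates = DotList(blobs.centroids)
    if d is None:
        d = default_distance_threshold(blobs.label_image > 0, max(blobs.n_blobs, 1))
    tp = count_true_positives(truth, candidates, d)
    return compute_metrics(tp, truth.count, candidates.count, d)


def summarize_batch(metrics: list[DetectionMetrics]) -> dict:
    """Mean and standard deviation of precision/recall/F over images.

    Undefined per-image precision/recall (empty candidate or truth lists)
    are treated as 0 in the averages, matching how an empty detection
    counts against a method.
    """
    if not metrics:
        raise ValueError("no metrics to summarize")

    def col(values):
        return np.nan_to_num(np.asarray(values, dtype=float), nan=0.0)

    p = col([m.precision for m in metrics])
    r = col([m.recall for m in metrics])
    f = np.asarray([m.f_score for m in metrics], dtype=float)
    return {
        "n_images": len(metrics),
        "precision_mean": float(p.mean()),
        "precision_std": float(p.std(ddof=0)),
        "recall_mean": float(r.mean()),
        "recall_std": float(r.std(ddof=0)),
        "f_score_mean": float(f.mean()),
        "f_score_std": float(f.std(ddof=0)),
    }
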