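"""Classification metrics, threshold sweeps and model ranking.

Model quality is summarized by three confusion-matrix metrics:

* MCC       = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))
* precision = TP / (TP + FP)
* recall    = TP / (TP + FN)

MCC is the primary selection metric: it uses all four confusion cells
and stays informative on imbalanced data, ranging from -1 (total
disagreement) through 0 (chance) to +1 (perfect).  Degenerate
denominators follow the standard conventions: MCC is 0 when any factor
under the root vanishes, precision/recall are 0 on a 0/0.

The active call at a probability-score threshold t is strict (PS > t);
the inclusive comparator used for screening hit selection lives in
:mod:`cdk9screen.screen`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_THRESHOLD_GRID = tuple(np.round(np.arange(0.50, 0.90001, 0.05), 2))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    mcc: float
    precision: float
    recall: float
    counts: ConfusionCounts


def confusion_at_threshold(
    ps: np.ndarray, labels: np.ndarray, t: float
) -> ConfusionCounts:
    """Count the confusion matrix for the strict active call PS > t.

    ``labels`` is a boolean/0-1 array (1 = active).  A score equal to
    the threshold is called inactive.
    """
    ps = np.asarray(ps, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if ps.shape != labels.shape:
        raise ValueError(f"length mismatch: {ps.shape} vs {labels.shape}")
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"threshold {t} outside [0,1]")
    pred = ps > t
    return ConfusionCounts(
        tp=int((pred & labels).sum()),
        tn=int((~pred & ~labels).sum()),
        fp=int((pred & ~labels).sum()),
        fn=int((~pred & labels).sum()),
    )


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when a denominator factor is 0."""
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom == 0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)


def precision(c: ConfusionCounts) -> float:
    denom = c.tp + c.fp
    return c.tp / denom if denom else 0.0


def recall(c: ConfusionCounts) -> float:
    denom = c.tp + c.fn
    return c.tp / denom if denom else 0.0


def metrics_report(ps: np.ndarray, labels: np.ndarray, t: float = 0.5) -> MetricsReport:
    c = confusion_at_threshold(ps, labels, t)
    return MetricsReport(mcc=mcc(c), precision=precision(c), recall=recall(c), counts=c)


@dataclass
class ThresholdCurve:
    """Precision/recall across a PS-threshold grid.

    ``table`` has columns threshold, mcc, precision, recall, n_selected;
    ``perfect_precision_threshold`` is the smallest grid threshold whose
    precision is exactly 1 (None if never reached).
    """

    table: pd.DataFrame
    perfect_precision_threshold: float | None


def sweep_thresholds(
    ps: np.ndarray,
    labels: np.ndarray,
    grid=DEFAULT_THRESHOLD_GRID,
) -> ThresholdCurve:
    """Evaluate the strict active call across a threshold grid.

    Recall is non-increasing in the threshold by construction; precision
    typically rises as low-confidence calls drop out.
    """
    rows = []
    perfect = None
    for t in sorted(grid):
        c = confusion_at_threshold(ps, labels, float(t))
        p = precision(c)
        rows.append(
            {
                "threshold": float(t),
                "mcc": mcc(c),
                "precision": p,
                "recall": recall(c),
                "n_selected": c.tp + c.fp,
            }
        )
        if perfect is None and p == 1.0 and (c.tp + c.fp) > 0:
            perfect = float(t)
    return ThresholdCurve(pd.DataFrame(rows), perfect)


def rank_models(reports: list[dict]) -> pd.DataFrame:
    """Rank model evaluation records by test MCC.

    Each record needs algorithm, representation, scheme, mcc, precision,
    recall.  Ties break by precision, then recall, then the lexicographic
    (algorithm, representation) name, making the table order independent
    of input order.
    """
    frame = pd.DataFrame(reports)
    if frame.empty:
        return frame
    frame = frame.sort_values(
        by=["mcc", "precision", "recall", "algorithm", "representation"],
        ascending=[False, False, False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    frame.index += 1
    frame.index.name = "rank"
    return frame
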