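"""Metrics and dataset audits for per-residue binding-site prediction.

Metrics are micro-averaged: confusion counts are pooled over all valid
residues of all proteins before MCC / precision / recall are computed,
matching the single-number-per-test-set reporting convention of the
binding-residue literature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ConfusionCounts",
    "DatasetSummary",
    "confusion",
    "mcc",
    "precision_recall",
    "threshold_sweep",
    "dataset_summary",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN over valid (non-padded) residues.

    TP counts binding residues predicted correctly; FP non-binding residues
    predicted as binding; TN non-binding predicted correctly; FN binding
    residues missed.
    """

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def degenerate(self) -> bool:
        """True when no residue was evaluated."""
        return self.total == 0

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)


def confusion(labels, predictions, mask=None) -> ConfusionCounts:
    """Tally TP/FP/TN/FN over mask-valid positions."""
    y = np.asarray(labels).astype(int).ravel()
    p = np.asarray(predictions).astype(int).ravel()
    if y.shape != p.shape:
        raise ValueError(f"labels and predictions differ in length: {y.shape} vs {p.shape}")
    if mask is None:
        valid = np.ones_like(y, dtype=bool)
    else:
        valid = np.asarray(mask, dtype=bool).ravel()
        if valid.shape != y.shape:
            raise ValueError("mask length must match labels")
    y, p = y[valid], p[valid]
    tp = int(np.sum((y == 1) & (p == 1)))
    fp = int(np.sum((y == 0) & (p == 1)))
    tn = int(np.sum((y == 0) & (p == 0)))
    fn = int(np.sum((y == 1) & (p == 0)))
    return ConfusionCounts(tp, fp, tn, fn)


def mcc(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient.

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); any zero
    factor in the denominator yields 0 by convention.
    """
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def precision_recall(counts: ConfusionCounts) -> tuple[float, float]:
    """Precision and recall as percentages; 0 when a denominator is zero."""
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    precision = 100.0 * tp / (tp + fp) if (tp + fp) > 0 else 0.0
    recall = 100.0 * tp / (tp + fn) if (tp + fn) > 0 else 0.0
    return precision, recall


DEFAULT_THRESHOLD_GRID = tuple(round(0.1 * i, 1) for i in range(1, 10))


def threshold_sweep(
    positive_probabilities,
    labels,
    mask=None,
    grid: Sequence[float] = DEFAULT_THRESHOLD_GRID,
) -> list[dict]:
    """Evaluate precision/recall/MCC over a grid of decision thresholds.

    A residue is predicted positive when its binding-class probability is
    >= the threshold, so the predicted-positive count (and hence recall)
    is non-increasing as the threshold increases.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("threshold grid is empty")
    if any(not (0.0 < t < 1.0) for t in grid):
        raise ValueError("thresholds must lie strictly in (0, 1)")
    scores = np.asarray(positive_probabilities, dtype=float).ravel()
    rows = []
    for t in grid:
        counts = confusion(labels, (scores >= t).astype(int), mask)
        prec, rec = precision_recall(counts)
        rows.append({
            "threshold": float(t),
            "precision": prec,
            "recall": rec,
            "mcc": mcc(counts),
            "predicted_positive": counts.tp + counts.fp,
        })
    return rows


@dataclass(frozen=True)
class DatasetSummary:
    """Size and class-skew audit of a labeled residue dataset."""

    n_prot: int
    n_br: int
    n_nbr: int
    p_br: float
    degenerate: bool = False


def _round2_half_up(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def dataset_summary(dataset=None, *, n_prot=None, n_br=None, n_nbr=None) -> DatasetSummary:
    """Summarize a labeled dataset: protein count, binding / non-binding
    residue counts and the binding-residue proportion.

    P_BR is reported as 100 * N_BR / N_NBR rounded half-up to two decimals
    (the ratio of binding to non-binding residues, the convention that the
    published dataset audits follow -- not BR / (BR + NBR)).

    Accepts either an iterable of labeled proteins (anything with a
    ``labels`` array) or explicit counts.
    """
    if dataset is not None:
        proteins = list(dataset)
        n_prot = len(proteins)
        n_br = n_nbr = 0
        for prot in proteins:
            labels = getattr(prot, "labels", None)
            if labels is None:
                raise ValueError("dataset_summary requires labels for every protein")
            labels = np.asarray(labels).astype(int)
            n_br += int((labels == 1).sum())
            n_nbr += int((labels == 0).sum())
    if n_prot is None or n_br is None or n_nbr is None:
        raise ValueError("provide a dataset or all of n_prot, n_br, n_nbr")
    if n_nbr == 0:
        return DatasetSummary(n_prot, n_br, n_nbr, p_br=0.0, degenerate=True)
    return DatasetSummary(n_prot, n_br, n_nbr, _round2_half_up(100.0 * n_br / n_nbr))
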