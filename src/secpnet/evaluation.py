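"""Segmentation evaluation: Dice, precision/recall, per-case vs global
aggregation, patient-level k-fold splits, repeated-run statistics and the
paired t-test protocol.

Dice is 2|A∩B| / (|A|+|B|) over the pixel sets predicted as / labelled as a
class.  "Dice per case" pools all slices of one patient volume, computes one
Dice per volume, and averages over volumes; "Dice global" pools every volume
into a single pair of pixel sets first.  Background-dominated metrics
(accuracy, specificity) are deliberately not implemented; background is
excluded from all reported means.

Undefined ratios (zero denominators) are returned as NaN and excluded from
averages rather than zero-filled.  The empty-vs-empty Dice is defined as 1
(with a flag available through :func:`confusion_counts`), which preserves
the identity Dice(A, A) = 1 universally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "confusion_counts",
    "dice_coefficient",
    "precision_recall",
    "dice_per_case_and_global",
    "kfold_split_patients",
    "paired_t_test",
    "aggregate_runs",
    "MetricsReport",
    "evaluate_masks",
]


def _check_same_shape(pred, truth):
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"mask shapes differ: {pred.shape} vs {truth.shape}")
    return pred, truth


def confusion_counts(pred, truth, num_classes: int) -> np.ndarray:
    """Per-class (TP, FP, FN) pixel counts as an (num_classes, 3) int array."""
    pred, truth = _check_same_shape(pred, truth)
    joint = np.bincount(
        (truth.ravel() * num_classes + pred.ravel()).astype(np.int64),
        minlength=num_classes * num_classes,
    ).reshape(num_classes, num_classes)  # rows: truth, cols: pred
    tp = np.diag(joint)
    fp = joint.sum(axis=0) - tp
    fn = joint.sum(axis=1) - tp
    return np.stack([tp, fp, fn], axis=1)


def dice_coefficient(pred, truth, cls: int) -> float:
    """Dice overlap for one class; both-empty masks score 1.0 by definition."""
    pred, truth = _check_same_shape(pred, truth)
    a = pred == cls
    b = truth == cls
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def precision_recall(tp: int, fp: int, fn: int) -> tuple:
    """Precision TP/(TP+FP) and recall TP/(TP+FN); a zero denominator yields
    NaN (undefined, excluded from averages)."""
    if tp < 0 or fp < 0 or fn < 0:
        raise ValueError(f"negative confusion counts: {(tp, fp, fn)}")
    precision = tp / (tp + fp) if tp + fp > 0 else math.nan
    recall = tp / (tp + fn) if tp + fn > 0 else math.nan
    return precision, recall


def dice_per_case_and_global(volumes, cls: int) -> tuple:
    """Dice per case and Dice global for one class over patient volumes.

    ``volumes`` is a sequence of (pred_stack, truth_stack) pairs, one per
    patient; stacks may be 2-D slices or 3-D slice stacks.
    """
    volumes = list(volumes)
    if not volumes:
        raise ValueError("need at least one volume")
    per_volume = []
    tp_pool = a_pool = b_pool = 0
    for pred, truth in volumes:
        pred, truth = _check_same_shape(pred, truth)
        a = pred == cls
        b = truth == cls
        na, nb = int(a.sum()), int(b.sum())
        inter = int((a & b).sum())
        per_volume.append(1.0 if na + nb == 0 else 2.0 * inter / (na + nb))
        tp_pool += inter
        a_pool += na
        b_pool += nb
    per_case = float(np.mean(per_volume))
    global_dice = 1.0 if a_pool + b_pool == 0 else 2.0 * tp_pool / (a_pool + b_pool)
    return per_case, global_dice


def kfold_split_patients(patient_ids, k: int = 5, seed: int = 0) -> list:
    """Disjoint, exhaustive patient-level folds with sizes differing by at
    most one; deterministic under ``seed``."""
    ids = list(patient_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("patient ids must be unique")
    if len(ids) < k:
        raise ValueError(f"need at least k={k} patients, got {len(ids)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    folds = [[] for _ in range(k)]
    for pos, idx in enumerate(order):
        folds[pos % k].append(ids[idx])
    return [sorted(f) for f in folds]


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    significant: bool
    degenerate: bool = False


def paired_t_test(scores_a, scores_b, alpha: float = 0.05) -> TTestResult:
    """Two-sided paired t-test on score differences.

    Zero-variance differences are degenerate: all-zero differences give
    p = 1 (not significant); constant nonzero differences give the p -> 0
    limit (significant), both flagged.
    """
    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"paired score lengths differ: {a.shape} vs {b.shape}")
    if a.ndim != 1 or len(a) < 2:
        raise ValueError("need 1-D paired scores with n >= 2")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0.0:
        if np.all(d == 0):
            return TTestResult(t=0.0, p=1.0, significant=False, degenerate=True)
        t = math.inf if d[0] > 0 else -math.inf
        return TTestResult(t=t, p=0.0, significant=True, degenerate=True)
    from scipy import stats

    t, p = stats.ttest_rel(a, b)
    return TTestResult(t=float(t), p=float(p), significant=bool(p < alpha))


@dataclass
class MetricsReport:
    """Per-class Dice/precision/recall plus background-excluded means.

    ``per_class`` is indexed by class label; class 0 (background) is kept in
    the table but excluded from every mean.  ``grouping`` records whether
    Dice values were pooled per case or globally.
    """

    per_class: pd.DataFrame  # index: class, columns: dice, precision, recall
    grouping: str = "per-case"

    def __post_init__(self):
        if self.grouping not in ("per-case", "global"):
            raise ValueError(f"unknown grouping {self.grouping!r}")

    def _foreground(self):
        return self.per_class.loc[self.per_class.index != 0]

    @property
    def mean_dice(self) -> float:
        return float(np.nanmean(self._foreground()["dice"]))

    @property
    def mean_precision(self) -> float:
        return float(np.nanmean(self._foreground()["precision"]))

    @property
    def mean_recall(self) -> float:
        return float(np.nanmean(self._foreground()["recall"]))

    def to_csv(self, path):
        self.per_class.to_csv(path, index_label="class")

    def to_dict(self):
        return {
            "grouping": self.grouping,
            "per_class": self.per_class.to_dict(orient="index"),
            "mean_dice": self.mean_dice,
            "mean_precision": self.mean_precision,
            "mean_recall": self.mean_recall,
        }


def evaluate_masks(volumes, num_classes: int, grouping: str = "per-case") -> MetricsReport:
    """Full metric report over patient volumes.

    Dice follows ``grouping`` (volume-pooled per case, then averaged, or
    globally pooled); precision/recall are always computed on the globally
    pooled confusion counts.
    """
    volumes = [tuple(_check_same_shape(p, t)) for p, t in volumes]
    if not volumes:
        raise ValueError("need at least one volume")
    counts = sum(confusion_counts(p, t, num_classes) for p, t in volumes)
    rows = {}
    for cls in range(num_classes):
        per_case, global_dice = dice_per_case_and_global(volumes, cls)
        tp, fp, fn = (int(v) for v in counts[cls])
        precision, recall = precision_recall(tp, fp, fn)
        rows[cls] = {
            "dice": per_case if grouping == "per-case" else global_dice,
            "precision": precision,
            "recall": recall,
            "tp": tp,
            "fp": fp,
            "fn": fn,
        }
    return MetricsReport(pd.DataFrame.from_dict(rows, orient="index"), grouping)


def aggregate_runs(runs) -> pd.DataFrame:
    """Entrywise mean and sample standard deviation over repeated runs.

    ``runs`` is a sequence of MetricsReport or per-class DataFrames with
    identical class sets; a single run yields std 0.  Returns a DataFrame
    with hierarchical columns (metric, {mean, std}).
    """
    frames = [
        r.per_class[["dice", "precision", "recall"]]
        if isinstance(r, MetricsReport)
        else pd.DataFrame(r)[["dice", "precision", "recall"]]
        for r in runs
    ]
    if not frames:
        raise ValueError("need at least one run")
    index = frames[0].index
    for f in frames[1:]:
        if not f.index.equals(index):
            raise ValueError("runs report inconsistent class sets")
    stacked = np.stack([f.to_numpy(dtype=float) for f in frames])  # (R, C, M)
    mean = stacked.mean(axis=0)
    std = stacked.std(axis=0, ddof=1) if len(frames) > 1 else np.zeros_like(mean)
    out = {}
    for j, metric in enumerate(frames[0].columns):
        out[(metric, "mean")] = mean[:, j]
        out[(metric, "std")] = std[:, j]
    return pd.DataFrame(out, index=index)
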