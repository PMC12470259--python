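"""Confusion-matrix segmentation metrics and the statistical validation
protocol (paired t-tests, 95% confidence intervals, subject-level k-fold CV).

All six overlap metrics derive from pixel-wise TP/FP/TN/FN counts:

    accuracy  = (TP + TN) / (TP + FP + TN + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)            (sensitivity)
    dice      = 2*TP / (2*TP + FP + FN)   (= F1 from a single count table)
    iou       = TP / (TP + FP + FN)       (Jaccard index)

Two aggregation modes are provided because F1 and Dice only diverge when
averaged differently: ``micro`` pools counts before computing metrics, and
``per_slice_mean`` averages per-slice metrics (with a configurable score for
slices whose truth and prediction are both empty).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateTestError, ValidationError


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        for name, v in (("tp", self.tp), ("fp", self.fp),
                        ("tn", self.tn), ("fn", self.fn)):
            if v < 0 or int(v) != v:
                raise ValidationError(f"{name} must be a nonnegative integer, got {v}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)


@dataclass(frozen=True)
class MetricReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    dice: float
    iou: float
    aggregation: str = "micro"
    n_slices: int = 1


@dataclass(frozen=True)
class StatTestConfig:
    alpha: float = 0.05
    k_folds: int = 5
    ci_level: float = 0.95
    split_unit: str = "subject"

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ValidationError("alpha must lie in (0, 1)")
        if self.k_folds < 2:
            raise ValidationError("k_folds must be >= 2")


def confusion_counts(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Pixel-wise tally of a binary prediction against a binary ground truth."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValidationError(
            f"prediction shape {pred.shape} != truth shape {truth.shape}")
    for name, arr in (("prediction", pred), ("truth", truth)):
        if not np.isin(arr, (0, 1)).all():
            raise ValidationError(f"{name} is not strictly binary")
    p = pred.astype(bool)
    t = truth.astype(bool)
    return ConfusionCounts(tp=int((p & t).sum()), fp=int((p & ~t).sum()),
                           tn=int((~p & ~t).sum()), fn=int((~p & t).sum()))


def compute_metrics(c: ConfusionCounts, degenerate_value: float = 1.0,
                    aggregation: str = "micro", n_slices: int = 1) -> MetricReport:
    """Evaluate all six metrics from one count table.

    Ratios with a zero denominator (possible only when the corresponding
    positive sets are empty) score ``degenerate_value`` — by default 1.0,
    i.e. an empty prediction of an empty truth is counted as perfect.
    """
    if c.total == 0:
        raise ValidationError("cannot compute metrics from all-zero counts")

    def ratio(num: float, den: float) -> float:
        return num / den if den > 0 else degenerate_value

    dice = ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn)
    return MetricReport(
        accuracy=(c.tp + c.tn) / c.total,
        precision=ratio(c.tp, c.tp + c.fp),
        recall=ratio(c.tp, c.tp + c.fn),
        f1=dice,
        dice=dice,
        iou=ratio(c.tp, c.tp + c.fp + c.fn),
        aggregation=aggregation,
        n_slices=n_slices,
    )


def aggregate(counts: Sequence[ConfusionCounts], mode: str = "micro",
              degenerate_value: float = 1.0) -> MetricReport:
    """Combine per-slice count tables.

    ``micro``: sum counts, then compute metrics once.
    ``per_slice_mean``: compute metrics per slice and average them.
    """
    counts = list(counts)
    if not counts:
        raise ValidationError("cannot aggregate an empty collection")
    if mode == "micro":
        total = counts[0]
        for c in counts[1:]:
            total = total + c
        r = compute_metrics(total, degenerate_value)
        return MetricReport(r.accuracy, r.precision, r.recall, r.f1, r.dice,
                            r.iou, "micro", len(counts))
    if mode == "per_slice_mean":
        reports = [compute_metrics(c, degenerate_value) for c in counts]
        mean = lambda f: float(np.mean([getattr(r, f) for r in reports]))
        return MetricReport(mean("accuracy"), mean("precision"), mean("recall"),
                            mean("f1"), mean("dice"), mean("iou"),
                            "per_slice_mean", len(counts))
    raise ValidationError(f"unknown aggregation mode {mode!r}")


def paired_t_test(scores_a: Sequence[float], scores_b: Sequence[float]
                  ) -> tuple[float, float]:
    """Two-sided paired t-test on per-subject metric pairs.

    Returns (t, p).  Identical lists give (0, 1); nonzero constant
    differences (zero variance) make the statistic undefined and raise
    :class:`DegenerateTestError`.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("paired score lists must be 1-D and equally long")
    if a.size < 3:
        raise ValidationError("paired t-test needs at least 3 pairs")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            return 0.0, 1.0
        raise DegenerateTestError(
            "paired differences have zero variance but nonzero mean")
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


def confidence_interval(scores: Sequence[float], level: float = 0.95
                        ) -> tuple[float, float]:
    """t-distribution confidence interval for the mean of a metric sample."""
    x = np.asarray(scores, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValidationError("confidence interval needs >= 2 observations")
    if not (0 < level < 1):
        raise ValidationError("level must lie in (0, 1)")
    mean = x.mean()
    sem = x.std(ddof=1) / np.sqrt(x.size)
    tcrit = stats.t.ppf(0.5 + level / 2.0, df=x.size - 1)
    half = tcrit * sem
    return float(mean - half), float(mean + half)


def kfold_split(subject_ids: Iterable[str], k: int = 5, seed: int = 0
                ) -> list[tuple[list[str], list[str]]]:
    """Subject-level k-fold partition with a seeded shuffle.

    Every subject lands in exactly one validation fold; fold sizes differ by
    at most one.  Returns ``[(train_ids, val_ids), ...]`` with k entries.
    """
    ids = list(subject_ids)
    if len(set(ids)) != len(ids):
        raise ValidationError("subject ids must be unique")
    if len(ids) < k:
        raise ValidationError(f"need at least k={k} subjects, got {len(ids)}")
    order = np.random.default_rng(seed).permutation(len(ids))
    shuffled = [ids[i] for i in order]
    folds = [list(f) for f in np.array_split(shuffled, k)]
    out = []
    for i in range(k):
        val = folds[i]
        train = [s for j, f in enumerate(folds) if j != i for s in f]
        out.append((train, val))
    return out
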