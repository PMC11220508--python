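"""Classification metrics, ROC/AUC, and permutation-test significance.

The positive class throughout is cMCI (label 1): sensitivity is the rate at
which eventual converters are flagged, specificity the rate at which stable
patients are cleared.  Balanced accuracy — the mean of the two — is the
model-selection metric for the whole pipeline, because the cohorts are
class-imbalanced and plain accuracy would reward always predicting sMCI.

Percent-scale metrics (sensitivity, specificity, balanced accuracy, NPV,
PPV) are reported on a 0–100 scale; F1 and AUC as fractions in [0, 1].
Ratios with a zero denominator (e.g. PPV when no sample is predicted
positive) are reported as NaN with a warning, never silently coerced to 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "PermutationResult",
    "confusion",
    "metric_suite",
    "balanced_accuracy",
    "roc_auc",
    "roc_points",
    "permutation_test",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion-table counts with cMCI (label 1) as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v}")
        if self.n == 0:
            raise ValueError("confusion counts must describe at least one sample")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """Metric suite on the percent scale (F1 and AUC as fractions).

    Undefined ratios are NaN.  ``auc`` is NaN unless probabilities were
    available to the caller (it is computed from scores, not counts).
    """

    balanced_accuracy: float
    sensitivity: float
    specificity: float
    f1: float
    npv: float
    ppv: float
    auc: float = math.nan

    def as_dict(self) -> dict[str, float]:
        return {
            "balanced_accuracy": self.balanced_accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "f1": self.f1,
            "npv": self.npv,
            "ppv": self.ppv,
            "auc": self.auc,
        }


@dataclass(frozen=True)
class PermutationResult:
    observed: float
    n_permutations: int
    p_raw: float
    p_adjusted: float


def _as_binary(values: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(values)
    if arr.size == 0:
        raise ValueError(f"{name} is empty")
    uniq = np.unique(arr)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValueError(f"{name} must be binary 0/1, got values {uniq}")
    return arr.astype(int)


def confusion(labels: Sequence[int], predictions: Sequence[int]) -> ConfusionCounts:
    """Tally the 2x2 confusion table (positive class = cMCI = 1)."""
    y = _as_binary(labels, "labels")
    p = _as_binary(predictions, "predictions")
    if y.shape != p.shape:
        raise ValueError("labels and predictions differ in length")
    tp = int(np.sum((y == 1) & (p == 1)))
    fp = int(np.sum((y == 0) & (p == 1)))
    tn = int(np.sum((y == 0) & (p == 0)))
    fn = int(np.sum((y == 1) & (p == 0)))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reported as NaN", RuntimeWarning)
        return math.nan
    return 100.0 * num / den


def metric_suite(counts: ConfusionCounts, auc: float = math.nan) -> MetricsReport:
    """Full metric suite from confusion counts.

    sensitivity = 100*tp/(tp+fn); specificity = 100*tn/(tn+fp);
    balanced accuracy = (sensitivity+specificity)/2; ppv = 100*tp/(tp+fp);
    npv = 100*tn/(tn+fn); f1 = 2*ppv*sen/(ppv+sen)/100, reported in [0, 1].
    """
    sen = _ratio(counts.tp, counts.tp + counts.fn, "sensitivity")
    spe = _ratio(counts.tn, counts.tn + counts.fp, "specificity")
    ppv = _ratio(counts.tp, counts.tp + counts.fp, "PPV")
    npv = _ratio(counts.tn, counts.tn + counts.fn, "NPV")
    bacc = (sen + spe) / 2.0
    if math.isnan(ppv) or math.isnan(sen):
        f1 = math.nan
    elif (ppv + sen) == 0:
        warnings.warn("F1 undefined (PPV + sensitivity is zero); reported as NaN", RuntimeWarning)
        f1 = math.nan
    else:
        f1 = 2.0 * ppv * sen / (ppv + sen) / 100.0
    return MetricsReport(
        balanced_accuracy=bacc, sensitivity=sen, specificity=spe,
        f1=f1, npv=npv, ppv=ppv, auc=auc,
    )


def balanced_accuracy(labels: Sequence[int], predictions: Sequence[int]) -> float:
    """Balanced accuracy on the percent scale; the pipeline's headline metric."""
    c = confusion(labels, predictions)
    sen = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else math.nan
    spe = c.tn / (c.tn + c.fp) if (c.tn + c.fp) else math.nan
    return 100.0 * (sen + spe) / 2.0


def roc_auc(labels: Sequence[int], probabilities: Sequence[float]) -> float:
    """Area under the ROC curve, Mann-Whitney formulation (ties count 1/2)."""
    y = _as_binary(labels, "labels")
    s = np.asarray(probabilities, dtype=float)
    if y.shape != s.shape:
        raise ValueError("labels and probabilities differ in length")
    if len(np.unique(y)) < 2:
        raise ValueError("roc_auc requires both classes present in labels")
    return float(roc_auc_score(y, s))


def roc_points(labels: Sequence[int], probabilities: Sequence[float]) -> np.ndarray:
    """Threshold-sweep ROC points as an (n_thresholds, 2) array of (FPR, TPR)."""
    y = _as_binary(labels, "labels")
    fpr, tpr, _ = roc_curve(y, np.asarray(probabilities, dtype=float))
    return np.column_stack([fpr, tpr])


def _balanced_accuracy_many(perm_labels: np.ndarray, predictions: np.ndarray) -> np.ndarray:
    """Balanced accuracy of fixed binary predictions against B permuted label rows."""
    pos = perm_labels == 1
    n_pos = pos.sum(axis=1)
    n_neg = perm_labels.shape[1] - n_pos
    tp = np.sum(pos & (predictions == 1), axis=1)
    tn = np.sum(~pos & (predictions == 0), axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sen = tp / n_pos
        spe = tn / n_neg
    return 100.0 * (sen + spe) / 2.0


def permutation_test(
    labels: Sequence[int],
    predictions_or_scores: Sequence[float],
    statistic: Optional[Callable[[np.ndarray, np.ndarray], float]] = None,
    B: int = 1000,
    seed: int = 0,
    n_comparisons: int = 1,
) -> PermutationResult:
    """Permutation significance of a fixed decision rule on the test set.

    Test labels are shuffled ``B`` times against the fixed predictions (or
    scores) and the statistic recomputed each time.  The add-one estimator
    ``p_raw = (1 + #{perm >= observed}) / (B + 1)`` keeps p strictly positive;
    ``p_adjusted = min(1, n_comparisons * p_raw)`` is the Bonferroni
    correction over the family of models evaluated together.

    The default statistic is balanced accuracy of binary predictions, for
    which the permutation sweep is vectorized.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    y = _as_binary(labels, "labels")
    v = np.asarray(predictions_or_scores)
    if y.shape != v.shape:
        raise ValueError("labels and predictions differ in length")
    rng = np.random.default_rng(seed)

    if statistic is None:
        preds = _as_binary(v, "predictions")
        observed = balanced_accuracy(y, preds)
        perm = np.array([rng.permutation(y) for _ in range(B)])
        null = _balanced_accuracy_many(perm, preds)
    else:
        observed = float(statistic(y, v))
        null = np.array([float(statistic(rng.permutation(y), v)) for _ in range(B)])

    n_ge = int(np.sum(null >= observed))
    p_raw = (1 + n_ge) / (B + 1)
    p_adj = min(1.0, n_comparisons * p_raw)
    return PermutationResult(observed=observed, n_permutations=B, p_raw=p_raw, p_adjusted=p_adj)
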