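"""Sensitive-biomarker selection: mRMR ranking plus BIC forward selection.

Each Hammers-atlas ROI is a candidate biomarker.  Features are first ranked
by a greedy minimum-redundancy-maximum-relevance (mRMR) scheme: relevance
is the one-way F statistic of the feature against the class label, and
redundancy is the mean absolute Pearson correlation with already-selected
features; each step picks the candidate maximizing relevance / redundancy
(the quotient scheme).  Models are then grown along the ranking — top-1
features, top-2, ... — re-tuning C by cross-validation for every subset
size, and the subset minimizing a BIC-style score

    BIC(k) = n * ln(L^2 / n) + k * ln(n),   L = 100 - balanced accuracy

is selected (ties toward the smaller subset).  The score trades residual
CV error against subset size, so parsimonious models win when extra ROIs
buy little accuracy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.feature_selection import f_classif

from .model import ModelSpec, tune_c

__all__ = [
    "FeatureRanking",
    "SubsetTrace",
    "mrmr_rank",
    "forward_subset_models",
    "bic_score",
    "select_subset",
    "REDUNDANCY_FLOOR",
    "LOSS_FLOOR",
]

#: Mean-|correlation| denominator floor, guarding against division blow-ups
#: for candidates nearly orthogonal to everything selected so far.
REDUNDANCY_FLOOR = 0.01

#: Loss floor (accuracy points): a perfect CV fit yields a large negative
#: but finite first BIC term instead of -inf.
LOSS_FLOOR = 0.1


@dataclass(frozen=True)
class FeatureRanking:
    ordered_features: tuple[str, ...]
    scores: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(set(self.ordered_features)) != len(self.ordered_features):
            raise ValueError("ordered_features must be a permutation (no repeats)")


@dataclass(frozen=True)
class SubsetTrace:
    """Per-subset-size record of CV balanced accuracy and BIC score."""

    entries: tuple[tuple[int, float, float], ...]  # (k, cv_balanced_accuracy, bic)
    selected_k: int


def mrmr_rank(
    train_matrix: np.ndarray,
    labels: Sequence[int],
    n_to_rank: Optional[int] = None,
    feature_names: Optional[Sequence[str]] = None,
) -> FeatureRanking:
    """Greedy mRMR ranking (F-statistic relevance / mean-|r| redundancy).

    The first pick maximizes marginal relevance; each later step maximizes
    relevance divided by mean absolute Pearson correlation with the features
    already selected.  Constant features have zero relevance and can never
    be ranked first.  Deterministic; ties resolve to the lower feature index.
    """
    X = np.asarray(train_matrix, dtype=float)
    y = np.asarray(labels, dtype=int)
    n, p = X.shape
    if p < 2:
        raise ValueError("mRMR needs at least 2 features")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    names = list(feature_names) if feature_names is not None else [f"f{j}" for j in range(p)]
    if len(names) != p:
        raise ValueError("feature_names length does not match feature count")
    k = p if n_to_rank is None else min(n_to_rank, p)

    with np.errstate(divide="ignore", invalid="ignore"):
        relevance, _ = f_classif(X, y)
    relevance = np.nan_to_num(relevance, nan=0.0, posinf=np.inf)
    if np.all(X.std(axis=0) == 0.0):
        raise ValueError("all features are constant; nothing to rank")

    # Pairwise |Pearson r|, with constant columns contributing 0 correlation.
    sd = X.std(axis=0)
    Xc = (X - X.mean(axis=0)) / np.where(sd == 0.0, 1.0, sd)
    corr = np.abs(Xc.T @ Xc / n)
    corr[:, sd == 0.0] = 0.0
    corr[sd == 0.0, :] = 0.0

    selected: list[int] = []
    scores: list[float] = []
    remaining = list(range(p))
    for step in range(k):
        if not selected:
            crit = relevance[remaining]
        else:
            red = np.maximum(corr[np.ix_(remaining, selected)].mean(axis=1), REDUNDANCY_FLOOR)
            crit = relevance[remaining] / red
        best = int(np.argmax(crit))  # argmax takes the first (lowest index) on ties
        scores.append(float(crit[best]))
        selected.append(remaining.pop(best))
    return FeatureRanking(
        ordered_features=tuple(names[j] for j in selected),
        scores=tuple(scores),
    )


def bic_score(n: int, balanced_accuracy: float, k: int) -> float:
    """BIC-style subset score; lower is better."""
    if n < 1 or k < 1:
        raise ValueError("n and k must be >= 1")
    if not 0.0 <= balanced_accuracy <= 100.0:
        raise ValueError(f"balanced_accuracy must be in [0, 100], got {balanced_accuracy}")
    L = max(100.0 - balanced_accuracy, LOSS_FLOOR)
    return n * math.log(L * L / n) + k * math.log(n)


def select_subset(trace: SubsetTrace | Sequence[tuple[int, float, float]]) -> int:
    """Subset size minimizing BIC; ties break toward the smallest k."""
    entries = trace.entries if isinstance(trace, SubsetTrace) else tuple(trace)
    if not entries:
        raise ValueError("empty subset trace")
    best_k, best_bic = None, math.inf
    for k, _, bic in entries:
        if bic < best_bic:
            best_k, best_bic = k, bic
    return best_k


def forward_subset_models(
    spec: ModelSpec,
    train_matrix: np.ndarray,
    labels: Sequence[int],
    ranking: FeatureRanking,
    seed: int = 0,
    feature_names: Optional[Sequence[str]] = None,
    max_k: Optional[int] = None,
) -> SubsetTrace:
    """Grow models along the ranking and score each subset size.

    For k = 1..K the model uses the top-k ranked features, re-running the
    cross-validated C search for every subset; the trace records each
    subset's mean CV balanced accuracy and BIC.  Deterministic given seed.
    """
    X = np.asarray(train_matrix, dtype=float)
    y = np.asarray(labels, dtype=int)
    names = list(feature_names) if feature_names is not None else [
        f"f{j}" for j in range(X.shape[1])
    ]
    index_of = {nm: j for j, nm in enumerate(names)}
    order = [index_of[nm] for nm in ranking.ordered_features]
    K = len(order) if max_k is None else min(max_k, len(order))
    n = X.shape[0]

    entries: list[tuple[int, float, float]] = []
    for k in range(1, K + 1):
        cols = order[:k]
        _, cv_bacc = tune_c(spec, X[:, cols], y, seed=seed)
        entries.append((k, cv_bacc, bic_score(n, cv_bacc, k)))
    trace = SubsetTrace(entries=tuple(entries), selected_k=0)
    return SubsetTrace(entries=trace.entries, selected_k=select_subset(trace.entries))
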