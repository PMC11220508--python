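"""Equal-weight late fusion of single-modality classifiers.

The ensemble probability for case ``i`` is the convex combination
``Y_i = sum_k c_k * y_ki`` of the member classifiers' predicted
probabilities, with weights summing to 1.  Equal weights are the default
(and the only mode used in replication reports): each modality acts as an
independent expert with the same say.  All subsets of size >= 2 of the four
imaging modalities give the 11 evaluated combinations (6 pairs, 4 triples,
1 quadruple).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io import FeatureMatrix
from .metrics import MetricsReport, confusion, metric_suite, roc_auc
from .model import TrainedModel, predict_proba

__all__ = [
    "EnsembleSpec",
    "fuse_probabilities",
    "enumerate_combinations",
    "evaluate_ensemble",
    "equal_weights",
]

_WEIGHT_TOL = 1e-12


def equal_weights(k: int) -> np.ndarray:
    return np.full(k, 1.0 / k)


@dataclass(frozen=True)
class EnsembleSpec:
    """A set of trained modality models fused with fixed weights."""

    members: tuple[TrainedModel, ...]
    weights: np.ndarray = None  # default: equal
    decision_threshold: float = 0.5

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("an ensemble needs at least 2 members")
        modalities = [m.spec.modality for m in self.members]
        if len(set(modalities)) != len(modalities):
            raise ValueError(f"ensemble members must have distinct modalities, got {modalities}")
        w = equal_weights(len(self.members)) if self.weights is None else np.asarray(
            self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        _check_weights(w, len(self.members))

    @property
    def name(self) -> str:
        return "+".join(m.spec.modality for m in self.members)


def _check_weights(weights: np.ndarray, k: int) -> None:
    if len(weights) != k:
        raise ValueError(f"got {len(weights)} weights for {k} members")
    if np.any(weights < 0) or np.any(weights > 1):
        raise ValueError("weights must lie in [0, 1]")
    if abs(float(weights.sum()) - 1.0) > _WEIGHT_TOL:
        raise ValueError(f"weights must sum to 1, got {weights.sum()!r}")


def fuse_probabilities(member_probs: np.ndarray, weights: Sequence[float]) -> np.ndarray:
    """Convex combination of member probabilities, one column per member."""
    P = np.asarray(member_probs, dtype=float)
    if P.ndim != 2:
        raise ValueError("member_probs must be an (n_samples, n_members) matrix")
    w = np.asarray(weights, dtype=float)
    _check_weights(w, P.shape[1])
    return P @ w


def enumerate_combinations(modalities: Sequence[str]) -> list[tuple[str, ...]]:
    """All subsets of size >= 2, ordered by size then input order.

    Four modalities yield the 11 evaluated combinations.
    """
    if len(set(modalities)) != len(modalities):
        raise ValueError(f"duplicate modality names: {list(modalities)}")
    out: list[tuple[str, ...]] = []
    for size in range(2, len(modalities) + 1):
        out.extend(itertools.combinations(modalities, size))
    return out


def evaluate_ensemble(
    spec: EnsembleSpec,
    test_matrices: Mapping[str, FeatureMatrix],
) -> MetricsReport:
    """Fuse member probabilities on aligned test visits and score them.

    ``test_matrices`` maps each member's modality to its test feature
    matrix; rows must describe the same (subject_id, visit_id) sequence for
    every member — the CVS guarantee.  A visit missing from any member's
    matrix is an error (fusion never imputes).  Fused probabilities at the
    decision threshold predict positive (cMCI).
    """
    keys = None
    for member in spec.members:
        mod = member.spec.modality
        if mod not in test_matrices:
            raise ValueError(f"no test matrix for member modality {mod!r}")
        fm = test_matrices[mod]
        k = list(zip(fm.subject_ids.tolist(), fm.visit_ids.tolist()))
        if keys is None:
            keys, ref_mod = k, mod
        elif k != keys:
            diff = set(keys).symmetric_difference(k)
            raise ValueError(
                f"test visits misaligned between {ref_mod!r} and {mod!r}: "
                f"offending visit(s) {sorted(diff)[:5]}"
            )
    member_probs = np.column_stack([
        predict_proba(member, test_matrices[member.spec.modality].values)
        for member in spec.members
    ])
    fused = fuse_probabilities(member_probs, spec.weights)
    labels = test_matrices[spec.members[0].spec.modality].labels
    preds = (fused >= spec.decision_threshold).astype(int)
    auc = roc_auc(labels, fused) if len(np.unique(labels)) == 2 else float("nan")
    return metric_suite(confusion(labels, preds), auc=auc)
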