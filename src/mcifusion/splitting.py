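"""IVS/CVS partition and repeated subject-level train/test splits.

Subjects with at least one visit carrying all required imaging modalities
form the Complete Visits Set (CVS); everyone else is in the Incomplete
Visits Set (IVS).  Because the late-fusion ensemble can only be evaluated
on visits where every member modality is present, test subjects are drawn
exclusively from the CVS: each repetition trains on all IVS subjects plus a
random 30% of CVS subjects (stratified by class) and tests on the remaining
70% of the CVS.  Splits are by participant, never by visit — all visits of
a test subject are test samples — which is the leakage guard that keeps
subject-level latent structure out of the training side.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .synthetic import Cohort, modality_of

__all__ = ["SplitPlan", "assign_ivs_cvs", "make_split", "DEFAULT_BASE_SEED", "DEFAULT_N_REPS"]

DEFAULT_BASE_SEED = 20240614
DEFAULT_N_REPS = 30


@dataclass(frozen=True)
class SplitPlan:
    rep_index: int
    seed: int
    train_subjects: frozenset[str]
    test_subjects: frozenset[str]

    def __post_init__(self) -> None:
        overlap = self.train_subjects & self.test_subjects
        if overlap:
            raise ValueError(f"subjects on both sides of the split: {sorted(overlap)}")

    def to_json(self) -> str:
        return json.dumps(
            {
                "rep_index": self.rep_index,
                "seed": self.seed,
                "train_subjects": sorted(self.train_subjects),
                "test_subjects": sorted(self.test_subjects),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SplitPlan":
        d = json.loads(text)
        return cls(
            rep_index=d["rep_index"], seed=d["seed"],
            train_subjects=frozenset(d["train_subjects"]),
            test_subjects=frozenset(d["test_subjects"]),
        )


def _visit_carries(visit_channels: Sequence[str], required: str) -> bool:
    # `required` may be a modality group (e.g. "smri") or a full channel name.
    return any(required == ch or required == modality_of(ch) for ch in visit_channels)


def assign_ivs_cvs(cohort: Cohort, required_modalities: Sequence[str]) -> dict[str, str]:
    """Label each subject 'CVS' or 'IVS'.

    A subject is CVS iff at least one of their visits carries every required
    modality simultaneously.  An empty CVS is allowed but flagged with a
    warning (downstream splitting will fail explicitly).
    """
    assignment: dict[str, str] = {sid: "IVS" for sid, _ in cohort.subjects}
    for visit in cohort.visits:
        chans = list(visit.features)
        if all(_visit_carries(chans, req) for req in required_modalities):
            assignment[visit.subject_id] = "CVS"
    if not any(v == "CVS" for v in assignment.values()):
        warnings.warn("CVS is empty: no subject has a visit with all required modalities",
                      RuntimeWarning)
    return assignment


def make_split(
    cohort: Cohort,
    ivs_cvs_map: Mapping[str, str],
    rep_index: int,
    base_seed: int = DEFAULT_BASE_SEED,
    cvs_train_fraction: float = 0.30,
) -> SplitPlan:
    """One repetition's subject-level split, seeded by ``base_seed + rep_index``.

    Train = all IVS subjects plus a stratified random ``cvs_train_fraction``
    of CVS subjects (rounded to nearest per class, always leaving at least
    one test subject per class); test = the remaining CVS subjects.
    """
    if not 0.0 <= cvs_train_fraction < 1.0:
        raise ValueError(f"cvs_train_fraction must be in [0, 1), got {cvs_train_fraction}")
    labels = cohort.labels()
    cvs = sorted(s for s, grp in ivs_cvs_map.items() if grp == "CVS")
    ivs = sorted(s for s, grp in ivs_cvs_map.items() if grp == "IVS")
    if not cvs:
        raise ValueError("cannot split: CVS is empty")
    seed = base_seed + rep_index
    rng = np.random.default_rng(seed)

    train: set[str] = set(ivs)
    test: set[str] = set()
    for cls in (0, 1):
        members = [s for s in cvs if labels[s] == cls]
        if not members:
            raise ValueError(f"CVS has no subject of class {cls}; cannot stratify the split")
        n_train = round(len(members) * cvs_train_fraction)
        n_train = min(n_train, len(members) - 1)  # keep >=1 test subject per class
        drawn = rng.choice(len(members), size=n_train, replace=False) if n_train else []
        drawn_set = {members[i] for i in drawn}
        train |= drawn_set
        test |= set(members) - drawn_set
    return SplitPlan(
        rep_index=rep_index, seed=seed,
        train_subjects=frozenset(train), test_subjects=frozenset(test),
    )
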