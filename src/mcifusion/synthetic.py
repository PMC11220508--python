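"""Synthetic multimodal ROI-feature cohorts.

Real MCI-conversion imaging cohorts (e.g. ADNI) are access-restricted, so
this module generates tabular cohorts with the statistical structure the
analysis pipeline assumes: two classes (stable vs. converted MCI), 64-ROI
feature vectors per modality/feature-map, repeated visits per subject,
class-dependent mean shifts on planted ROI subsets, tunable cross-modality
redundancy, and the complete/incomplete-visit missingness pattern that
drives the CVS/IVS partition.

Generative model, per subject ``s`` with class label ``z_s`` (0 = sMCI,
1 = cMCI): each imaging modality ``m`` carries a subject-level severity
factor ``u_{s,m} = sqrt(rho)*g_s + sqrt(1-rho)*e_{s,m}`` where ``g_s`` and
``e_{s,m}`` are independent standard normals, so that
``corr(u_{s,m}, u_{s,m'}) = rho`` for distinct modalities.  Feature ``j``
of channel ``c`` (a modality/feature-map pair) at a visit is

    x = sqrt(1 - lambda^2) * eps            (non-planted ROI)
    x = sqrt(1 - lambda^2) * eps + d_c * z_s + lambda * u_{s,m}   (planted)

with ``eps`` i.i.d. standard normal per visit and ``lambda = 0.5``.  The
non-class noise on a planted ROI then has unit variance for every value of
``rho``, so the empirical standardized group difference (Cohen's d) on
planted ROIs converges to the configured effect size ``d_c``.

Visits of one subject share ``z_s`` and ``u_{s,m}``; only ``eps`` is
redrawn per visit.  This encodes the subject-level leakage risk that the
subject-wise train/test split must neutralize.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import FeatureMatrix, default_roi_names, read_feature_table, write_feature_table

__all__ = [
    "SIGNAL_LOADING",
    "DEFAULT_CHANNELS",
    "SyntheticConfig",
    "Visit",
    "Cohort",
    "generate_cohort",
    "cohort_to_feature_matrices",
    "write_cohort",
    "read_cohort",
    "modality_of",
]

#: Loading of the shared severity factor on planted ROIs; chosen so the
#: total planted-feature noise variance is 1 for every redundancy setting.
SIGNAL_LOADING = 0.5

#: The twelve modality/feature-map channels of the full study design:
#: structural MRI grey/white matter volumes, AV45- and FDG-PET SUVR with
#: four reference regions each, and DTI FA/MD.
DEFAULT_CHANNELS = (
    "smri-gm", "smri-wm",
    "av45-cerebellum", "av45-gm", "av45-wm", "av45-pons",
    "fdg-cerebellum", "fdg-gm", "fdg-wm", "fdg-pons",
    "dti-fa", "dti-md",
)

# Default per-channel effect sizes mirror the qualitative ordering of
# modality informativeness in MCI-conversion cohorts: amyloid PET strongest,
# grey-matter volumetry and FDG metabolism intermediate, white-matter
# volumetry and diffusion metrics weak.
_DEFAULT_EFFECTS = {
    "smri-gm": 0.9, "smri-wm": 0.3,
    "av45-cerebellum": 1.3, "av45-gm": 1.3, "av45-wm": 1.2, "av45-pons": 1.25,
    "fdg-cerebellum": 0.7, "fdg-gm": 0.8, "fdg-wm": 0.75, "fdg-pons": 0.7,
    "dti-fa": 0.2, "dti-md": 0.25,
}


def modality_of(channel: str) -> str:
    """Modality group of a channel name (prefix before the first '-')."""
    return channel.split("-", 1)[0]


def _default_planted(channels: Sequence[str], n_rois: int) -> dict[str, frozenset[int]]:
    # Ten planted ROIs per channel; modalities get staggered (partially
    # overlapping) subsets so the default cohort carries complementary signal.
    offsets = {m: 6 * i for i, m in enumerate(dict.fromkeys(modality_of(c) for c in channels))}
    return {
        c: frozenset(range(offsets[modality_of(c)], offsets[modality_of(c)] + 10))
        for c in channels
        if max(range(offsets[modality_of(c)], offsets[modality_of(c)] + 10)) < n_rois
    }


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic cohort generator.

    Defaults mirror the scale of the published MCI-conversion cohort:
    486 subjects of whom 234 convert, and roughly 92 subjects (19%) with at
    least one visit carrying all four imaging modalities.
    """

    n_subjects: int = 486
    frac_converted: float = 234 / 486
    visits_per_subject: int = 2
    n_rois: int = 64
    modalities: tuple[str, ...] = DEFAULT_CHANNELS
    planted_rois: Mapping[str, frozenset[int]] | None = None
    effect_size: Mapping[str, float] | None = None
    redundancy_rho: float = 0.5
    frac_complete: float = 92 / 486
    missing_modality_rate: float = 0.6
    seed: int = 0

    def resolved_planted(self) -> dict[str, frozenset[int]]:
        if self.planted_rois is None:
            return _default_planted(self.modalities, self.n_rois)
        return {c: frozenset(v) for c, v in self.planted_rois.items()}

    def resolved_effects(self) -> dict[str, float]:
        if self.effect_size is None:
            return {c: _DEFAULT_EFFECTS.get(c, 0.5) for c in self.modalities}
        return dict(self.effect_size)

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ValueError(f"n_subjects must be >= 2, got {self.n_subjects}")
        for name in ("frac_converted", "frac_complete", "missing_modality_rate", "redundancy_rho"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.visits_per_subject < 1:
            raise ValueError(f"visits_per_subject must be >= 1, got {self.visits_per_subject}")
        if self.n_rois < 1:
            raise ValueError(f"n_rois must be >= 1, got {self.n_rois}")
        if len(set(self.modalities)) != len(self.modalities):
            raise ValueError("modalities contains duplicate channel names")
        n_converted = round(self.n_subjects * self.frac_converted)
        if n_converted == 0 or n_converted == self.n_subjects:
            raise ValueError(
                f"frac_converted={self.frac_converted} leaves a class empty at "
                f"n_subjects={self.n_subjects}"
            )
        for c, rois in self.resolved_planted().items():
            if c not in self.modalities:
                raise ValueError(f"planted_rois names unknown channel {c!r}")
            bad = [j for j in rois if not 0 <= j < self.n_rois]
            if bad:
                raise ValueError(f"planted_rois[{c!r}] indices out of range: {bad}")
        for c in self.resolved_effects():
            if c not in self.modalities:
                raise ValueError(f"effect_size names unknown channel {c!r}")


@dataclass(frozen=True)
class Visit:
    subject_id: str
    visit_id: str
    features: Mapping[str, np.ndarray]  # channel -> length-n_rois vector


@dataclass(frozen=True)
class Cohort:
    """Subjects with class labels plus per-visit, per-channel ROI features."""

    subjects: tuple[tuple[str, int], ...]  # (subject_id, label)
    visits: tuple[Visit, ...]
    n_rois: int
    channels: tuple[str, ...]

    def labels(self) -> dict[str, int]:
        return dict(self.subjects)

    def visits_of(self, subject_id: str) -> list[Visit]:
        return [v for v in self.visits if v.subject_id == subject_id]

    def validate(self) -> None:
        known = {s for s, _ in self.subjects}
        seen = set()
        for v in self.visits:
            if v.subject_id not in known:
                raise ValueError(f"visit {v.visit_id} references unknown subject {v.subject_id}")
            seen.add(v.subject_id)
            for ch, vec in v.features.items():
                if len(vec) != self.n_rois:
                    raise ValueError(f"visit {v.visit_id} channel {ch} has wrong length")
        missing = known - seen
        if missing:
            raise ValueError(f"subjects without any visit: {sorted(missing)}")


def generate_cohort(config: SyntheticConfig) -> Cohort:
    """Draw a cohort from the latent-factor generative model (seeded)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    n_converted = round(n * config.frac_converted)
    labels = np.zeros(n, dtype=int)
    labels[:n_converted] = 1
    rng.shuffle(labels)

    subject_ids = [f"S{i:04d}" for i in range(n)]
    channels = tuple(config.modalities)
    groups = list(dict.fromkeys(modality_of(c) for c in channels))
    planted = config.resolved_planted()
    effects = config.resolved_effects()
    rho = config.redundancy_rho
    lam = SIGNAL_LOADING

    # Subject-level latents: shared severity g and per-modality factors u.
    g = rng.standard_normal(n)
    e = rng.standard_normal((n, len(groups)))
    u = np.sqrt(rho) * g[:, None] + np.sqrt(1.0 - rho) * e

    # Completeness assignment.
    n_complete = round(n * config.frac_complete)
    complete_ids = set(rng.choice(n, size=n_complete, replace=False)) if n_complete else set()

    visits: list[Visit] = []
    for i, sid in enumerate(subject_ids):
        for t in range(config.visits_per_subject):
            present = _present_modalities(
                groups, complete=i in complete_ids,
                rate=config.missing_modality_rate, rng=rng,
            )
            feats: dict[str, np.ndarray] = {}
            for ci, ch in enumerate(channels):
                if modality_of(ch) not in present:
                    continue
                x = np.sqrt(1.0 - lam**2) * rng.standard_normal(config.n_rois)
                rois = planted.get(ch, frozenset())
                if rois:
                    idx = np.fromiter(rois, dtype=int)
                    gi = groups.index(modality_of(ch))
                    x[idx] += effects.get(ch, 0.0) * labels[i] + lam * u[i, gi]
                feats[ch] = x
            visits.append(Visit(subject_id=sid, visit_id=f"V{t:02d}", features=feats))

    cohort = Cohort(
        subjects=tuple(zip(subject_ids, labels.tolist())),
        visits=tuple(visits), n_rois=config.n_rois, channels=channels,
    )
    cohort.validate()
    return cohort


def _present_modalities(groups: Sequence[str], complete: bool, rate: float,
                        rng: np.random.Generator) -> set[str]:
    """Modalities recorded at one visit.

    Complete subjects carry every modality at every visit.  Incomplete
    subjects drop each modality independently with the configured rate, but
    every visit keeps at least one modality and (to keep the subject out of
    the complete-visits set) at least one modality missing.
    """
    if complete or len(groups) == 1:
        return set(groups)
    drop = rng.random(len(groups)) < rate
    if drop.all():
        drop[rng.integers(len(groups))] = False
    if not drop.any():
        drop[rng.integers(len(groups))] = True
    return {m for m, d in zip(groups, drop) if not d}


def cohort_to_feature_matrices(cohort: Cohort) -> dict[str, FeatureMatrix]:
    """One feature matrix per channel, rows sorted by (subject_id, visit_id).

    A channel absent from every visit yields an empty (0-row) matrix rather
    than an error; callers check ``FeatureMatrix.is_empty``.
    """
    labels = cohort.labels()
    names = default_roi_names(cohort.n_rois)
    ordered = sorted(cohort.visits, key=lambda v: (v.subject_id, v.visit_id))
    out: dict[str, FeatureMatrix] = {}
    for ch in cohort.channels:
        rows = [v for v in ordered if ch in v.features]
        values = np.array([v.features[ch] for v in rows]) if rows else np.empty((0, cohort.n_rois))
        out[ch] = FeatureMatrix(
            values=values, feature_names=names,
            labels=np.array([labels[v.subject_id] for v in rows], dtype=int),
            subject_ids=np.array([v.subject_id for v in rows], dtype=object),
            visit_ids=np.array([v.visit_id for v in rows], dtype=object),
            modality=modality_of(ch),
            feature_map=ch.split("-", 1)[1] if "-" in ch else ch,
        )
    return out


def write_cohort(cohort: Cohort, directory: str | Path) -> None:
    """Write one CSV per channel plus a subjects.csv manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for ch, fm in cohort_to_feature_matrices(cohort).items():
        write_feature_table(fm, directory / f"{ch}.csv")
    pd.DataFrame(cohort.subjects, columns=["subject_id", "label"]).to_csv(
        directory / "subjects.csv", index=False
    )


def read_cohort(directory: str | Path, channels: Sequence[str] | None = None) -> Cohort:
    """Reassemble a cohort from per-channel CSVs written by :func:`write_cohort`."""
    directory = Path(directory)
    manifest = pd.read_csv(directory / "subjects.csv")
    subjects = tuple((str(r.subject_id), int(r.label)) for r in manifest.itertuples())
    if channels is None:
        channels = sorted(p.stem for p in directory.glob("*.csv") if p.stem != "subjects")
    visit_feats: dict[tuple[str, str], dict[str, np.ndarray]] = {}
    n_rois = 0
    for ch in channels:
        fm = read_feature_table(directory / f"{ch}.csv", modality=modality_of(ch))
        n_rois = fm.n_features
        for i in range(fm.n_samples):
            key = (str(fm.subject_ids[i]), str(fm.visit_ids[i]))
            visit_feats.setdefault(key, {})[ch] = fm.values[i]
    visits = tuple(
        Visit(subject_id=sid, visit_id=vid, features=feats)
        for (sid, vid), feats in sorted(visit_feats.items())
    )
    cohort = Cohort(subjects=subjects, visits=visits, n_rois=n_rois, channels=tuple(channels))
    cohort.validate()
    return cohort
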