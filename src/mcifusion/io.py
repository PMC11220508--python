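"""Data model, ROI feature-table I/O, and feature-level arithmetic.

Each modality/feature-map (e.g. structural-MRI grey matter, AV45-PET SUVR
with the cerebellum reference, DTI fractional anisotropy) lives in its own
table: one row per visit, columns ``subject_id, visit_id, label`` followed
by the 64 Hammers-atlas ROI features.  The two feature-level computations
from the acquisition side of the pipeline are also here: SUVR (mean tracer
uptake of a region divided by that of a reference region) and TIV
normalization (regional volume divided by total intracranial volume, which
removes head-size differences).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "REFERENCE_REGIONS",
    "FeatureMatrix",
    "RoiUptakeRecord",
    "RoiVolumeRecord",
    "compute_suvr",
    "normalize_by_tiv",
    "read_feature_table",
    "write_feature_table",
    "default_roi_names",
]

#: PET reference regions available for SUVR construction.
REFERENCE_REGIONS = ("cerebellum", "gm", "wm", "pons")

_META_COLUMNS = ("subject_id", "visit_id", "label")


def default_roi_names(n_rois: int = 64) -> list[str]:
    """Positional ROI column names roi_000..roi_NNN."""
    return [f"roi_{i:03d}" for i in range(n_rois)]


@dataclass
class FeatureMatrix:
    """Samples-by-ROI feature matrix for one modality/feature-map.

    ``labels`` are 0 for stable MCI and 1 for converted MCI; ``subject_ids``
    and ``visit_ids`` are carried alongside so subject-level splitting and
    cross-modality row alignment stay possible downstream.
    """

    values: np.ndarray
    feature_names: list[str]
    labels: np.ndarray
    subject_ids: np.ndarray
    visit_ids: np.ndarray
    modality: str = ""
    feature_map: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.subject_ids = np.asarray(self.subject_ids)
        self.visit_ids = np.asarray(self.visit_ids)
        n, p = self.values.shape if self.values.ndim == 2 else (len(self.values), 0)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D samples x features matrix")
        if len(self.feature_names) != p:
            raise ValueError("feature_names length does not match feature count")
        if len(set(self.feature_names)) != p:
            raise ValueError("feature_names must be unique")
        for name, arr in (("labels", self.labels), ("subject_ids", self.subject_ids),
                          ("visit_ids", self.visit_ids)):
            if len(arr) != n:
                raise ValueError(f"{name} length does not match sample count")
        if n and not np.all(np.isin(np.unique(self.labels), (0, 1))):
            raise ValueError("labels must contain only 0 (sMCI) and 1 (cMCI)")
        if n and not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains missing or non-finite entries")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def is_empty(self) -> bool:
        return self.n_samples == 0

    def subset_rows(self, mask: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            values=self.values[mask], feature_names=list(self.feature_names),
            labels=self.labels[mask], subject_ids=self.subject_ids[mask],
            visit_ids=self.visit_ids[mask], modality=self.modality,
            feature_map=self.feature_map,
        )

    def subset_features(self, names: Sequence[str]) -> "FeatureMatrix":
        idx = [self.feature_names.index(n) for n in names]
        return FeatureMatrix(
            values=self.values[:, idx], feature_names=list(names),
            labels=self.labels, subject_ids=self.subject_ids,
            visit_ids=self.visit_ids, modality=self.modality,
            feature_map=self.feature_map,
        )


@dataclass(frozen=True)
class RoiUptakeRecord:
    """Mean PET tracer uptake per ROI plus the four reference-region means."""

    roi_means: np.ndarray
    reference_means: Mapping[str, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "roi_means", np.asarray(self.roi_means, dtype=float))
        for name, v in self.reference_means.items():
            if not v > 0:
                raise ValueError(f"reference mean for {name!r} must be positive, got {v}")


@dataclass(frozen=True)
class RoiVolumeRecord:
    """Regional tissue volumes (mL) and total intracranial volume (mL)."""

    roi_volumes: np.ndarray
    tiv: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "roi_volumes", np.asarray(self.roi_volumes, dtype=float))
        if not self.tiv > 0:
            raise ValueError(f"TIV must be positive, got {self.tiv}")
        if np.any(self.roi_volumes < 0):
            raise ValueError("ROI volumes must be non-negative")


def compute_suvr(record: RoiUptakeRecord, reference: str) -> np.ndarray:
    """Standard uptake value ratio: ROI means divided by a reference mean."""
    if reference not in record.reference_means:
        valid = sorted(record.reference_means)
        raise ValueError(f"unknown reference {reference!r}; valid references: {valid}")
    ref = record.reference_means[reference]
    return record.roi_means / ref


def normalize_by_tiv(record: RoiVolumeRecord) -> np.ndarray:
    """Head-size correction: regional volumes as fractions of TIV."""
    return record.roi_volumes / record.tiv


def _delimiter_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def write_feature_table(matrix: FeatureMatrix, path: str | Path) -> None:
    """Write a feature matrix as CSV/TSV (delimiter inferred from extension)."""
    path = Path(path)
    df = pd.DataFrame(matrix.values, columns=matrix.feature_names)
    df.insert(0, "label", matrix.labels)
    df.insert(0, "visit_id", matrix.visit_ids)
    df.insert(0, "subject_id", matrix.subject_ids)
    # repr gives the shortest decimal that round-trips IEEE doubles exactly
    df.to_csv(path, sep=_delimiter_for(path), index=False, float_format=lambda x: repr(float(x)))


def read_feature_table(path: str | Path, modality: str = "", feature_map: str = "") -> FeatureMatrix:
    """Read a per-modality ROI feature table.

    Requires columns ``subject_id, visit_id, label``; every remaining column
    is a numeric ROI feature.  Duplicate ``(subject_id, visit_id)`` rows and
    non-numeric feature cells raise with the offending row index.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter_for(path), float_precision="round_trip")
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required column(s) {missing}")
    feature_cols = [c for c in df.columns if c not in _META_COLUMNS]
    dup = df.duplicated(subset=["subject_id", "visit_id"])
    if dup.any():
        rows = df.index[dup].tolist()
        raise ValueError(f"{path.name}: duplicate (subject_id, visit_id) at row(s) {rows}")
    values = df[feature_cols].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = np.where(~np.isfinite(values).all(axis=1))[0]
    if bad.size:
        raise ValueError(f"{path.name}: non-numeric or missing feature cell(s) at row(s) {bad.tolist()}")
    return FeatureMatrix(
        values=values, feature_names=feature_cols,
        labels=df["label"].to_numpy(), subject_ids=df["subject_id"].to_numpy(),
        visit_ids=df["visit_id"].to_numpy(), modality=modality, feature_map=feature_map,
    )
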