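"""End-to-end experiment driver.

Runs the full repeated-holdout design: for each repetition, a fresh
subject-level split, one classifier per modality/feature-map and kernel,
single-modality evaluation with permutation significance, equal-weight
fusion of the per-modality best models over every modality combination,
and the mRMR + BIC sensitive-biomarker arm.  Metrics are averaged across
repetitions (mean of per-repetition metrics, not pooled confusion counts),
with both the standard error and standard deviation stored; tables print
mean +/- SE by default.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .fusion import EnsembleSpec, enumerate_combinations, evaluate_ensemble
from .io import FeatureMatrix
from .metrics import confusion, metric_suite, permutation_test, roc_auc, roc_points
from .model import ModelSpec, TrainedModel, fit_model, predict_labels, predict_proba
from .selection import forward_subset_models, mrmr_rank, select_subset
from .splitting import (DEFAULT_BASE_SEED, DEFAULT_N_REPS, SplitPlan,
                        assign_ivs_cvs, make_split)
from .synthetic import (Cohort, SyntheticConfig, cohort_to_feature_matrices,
                        generate_cohort, modality_of, read_cohort)

logger = logging.getLogger("mcifusion")

__all__ = ["RunConfig", "AggregateReport", "run_experiment", "select_best_per_modality",
           "default_model_specs", "write_report"]

_METRIC_COLS = ("balanced_accuracy", "sensitivity", "specificity", "f1", "npv", "ppv", "auc")


def default_model_specs(channels: Sequence[str],
                        c_search: tuple[float, float, int] = (1e-3, 1e3, 50),
                        cv_folds: int = 10) -> list[ModelSpec]:
    """Two kernels (linear, RBF) for every modality/feature-map channel."""
    specs = []
    for ch in channels:
        mod = modality_of(ch)
        fmap = ch.split("-", 1)[1] if "-" in ch else ch
        for kernel in ("linear", "rbf"):
            specs.append(ModelSpec(modality=mod, feature_map=fmap, kernel=kernel,
                                   c_search=c_search, cv_folds=cv_folds))
    return specs


@dataclass
class RunConfig:
    """Configuration of a full experiment run."""

    synthetic: Optional[SyntheticConfig] = None
    cohort_dir: Optional[str] = None
    model_specs: Optional[list[ModelSpec]] = None
    n_reps: int = DEFAULT_N_REPS
    base_seed: int = DEFAULT_BASE_SEED
    permutation_B: int = 1000
    cvs_train_fraction: float = 0.30
    run_selection_arm: bool = True
    selection_max_k: Optional[int] = None
    out_dir: Optional[str] = None

    def load_cohort(self) -> Cohort:
        if self.synthetic is not None:
            return generate_cohort(self.synthetic)
        if self.cohort_dir is not None:
            return read_cohort(self.cohort_dir)
        raise ValueError("RunConfig needs either a synthetic config or a cohort directory")


@dataclass
class AggregateReport:
    """Across-repetition aggregates plus the per-repetition records."""

    singles: pd.DataFrame
    combinations: pd.DataFrame
    subsets: pd.DataFrame
    best_per_modality: dict[str, tuple[str, str]]
    per_rep_singles: pd.DataFrame
    per_rep_combinations: pd.DataFrame
    per_rep_subsets: pd.DataFrame
    feature_importance: pd.DataFrame
    n_reps: int
    # diagnostic curves from the first repetition, for figures
    roc_curves_singles: dict = field(default_factory=dict)
    roc_curves_combinations: dict = field(default_factory=dict)
    subset_traces: dict = field(default_factory=dict)


def _channel(spec: ModelSpec) -> str:
    return f"{spec.modality}-{spec.feature_map}" if spec.feature_map != spec.modality else spec.modality


def _rows_for_subjects(fm: FeatureMatrix, subjects: frozenset[str]) -> FeatureMatrix:
    mask = np.isin(fm.subject_ids.astype(str), sorted(subjects))
    return fm.subset_rows(mask)


def _complete_visit_matrices(
    matrices: Mapping[str, FeatureMatrix],
    channels: Sequence[str],
    subjects: frozenset[str],
) -> dict[str, FeatureMatrix]:
    """Per-channel matrices restricted to visits carrying every channel.

    Rows come out aligned on (subject_id, visit_id) across all channels,
    which is what the ensemble evaluation requires.
    """
    key_sets = []
    for ch in channels:
        fm = matrices[ch]
        keys = {(str(s), str(v)) for s, v in zip(fm.subject_ids, fm.visit_ids)
                if str(s) in subjects}
        key_sets.append(keys)
    common = sorted(set.intersection(*key_sets)) if key_sets else []
    out = {}
    for ch in channels:
        fm = matrices[ch]
        index = {(str(s), str(v)): i for i, (s, v) in enumerate(zip(fm.subject_ids, fm.visit_ids))}
        rows = np.array([index[k] for k in common], dtype=int)
        mask = np.zeros(fm.n_samples, dtype=bool)
        mask[rows] = True
        # subset_rows keeps the original order, which is (subject, visit)
        # sorted, identical to `common`'s ordering.
        out[ch] = fm.subset_rows(mask)
    return out


def select_best_per_modality(singles_agg: pd.DataFrame) -> dict[str, tuple[str, str]]:
    """Per modality, the (feature_map, kernel) with highest mean balanced
    accuracy; ties resolve lexicographically (and are logged)."""
    best: dict[str, tuple[str, str]] = {}
    for modality, grp in singles_agg.groupby("modality"):
        top = grp["balanced_accuracy_mean"].max()
        winners = grp[grp["balanced_accuracy_mean"] == top]
        winners = winners.sort_values(["feature_map", "kernel"])
        if len(winners) > 1:
            logger.info("tie for best %s model; taking lexicographic first", modality)
        row = winners.iloc[0]
        best[str(modality)] = (str(row["feature_map"]), str(row["kernel"]))
    return best


def _aggregate(per_rep: pd.DataFrame, keys: list[str], n_reps: int) -> pd.DataFrame:
    if per_rep.empty:
        return per_rep
    cols = [c for c in per_rep.columns
            if c not in keys + ["rep_index"] and pd.api.types.is_numeric_dtype(per_rep[c])]
    out = []
    for key_vals, grp in per_rep.groupby(keys, sort=False):
        if len(grp) != n_reps:
            logger.warning("aggregate over %d entries, expected %d reps", len(grp), n_reps)
        rec = dict(zip(keys, key_vals if isinstance(key_vals, tuple) else (key_vals,)))
        for c in cols:
            vals = grp[c].to_numpy(dtype=float)
            rec[f"{c}_mean"] = float(np.nanmean(vals))
            rec[f"{c}_sd"] = float(np.nanstd(vals, ddof=1)) if len(vals) > 1 else 0.0
            rec[f"{c}_se"] = rec[f"{c}_sd"] / np.sqrt(len(vals))
        out.append(rec)
    return pd.DataFrame(out)


def _evaluate_single(model: TrainedModel, test_fm: FeatureMatrix,
                     B: int, seed: int, n_comparisons: int) -> dict:
    probs = predict_proba(model, test_fm.values)
    preds = (probs >= 0.5).astype(int)
    auc = roc_auc(test_fm.labels, probs) if len(np.unique(test_fm.labels)) == 2 else np.nan
    rep = metric_suite(confusion(test_fm.labels, preds), auc=auc)
    perm = permutation_test(test_fm.labels, preds, B=B, seed=seed,
                            n_comparisons=n_comparisons)
    d = rep.as_dict()
    d["p_raw"] = perm.p_raw
    d["p_adjusted"] = perm.p_adjusted
    d["c_value"] = model.c_value
    d["cv_balanced_accuracy"] = model.cv_balanced_accuracy
    return d


def run_experiment(config: RunConfig) -> AggregateReport:
    """Run the full repeated-split experiment and aggregate all arms."""
    cohort = config.load_cohort()
    matrices = cohort_to_feature_matrices(cohort)
    channels = [ch for ch in cohort.channels if not matrices[ch].is_empty]
    specs = config.model_specs or default_model_specs(channels)
    modality_groups = list(dict.fromkeys(s.modality for s in specs))
    ivs_cvs = assign_ivs_cvs(cohort, modality_groups)

    singles_rows: list[dict] = []
    rep_models: list[dict[str, TrainedModel]] = []  # spec.name -> model, per rep
    splits: list[SplitPlan] = []
    roc_singles: dict[str, np.ndarray] = {}
    roc_combos: dict[str, np.ndarray] = {}
    subset_traces: dict[str, tuple] = {}

    for rep in range(config.n_reps):
        split = make_split(cohort, ivs_cvs, rep, config.base_seed, config.cvs_train_fraction)
        splits.append(split)
        models: dict[str, TrainedModel] = {}
        for si, spec in enumerate(specs):
            ch = _channel(spec)
            fm = matrices[ch]
            train_fm = _rows_for_subjects(fm, split.train_subjects)
            test_fm = _rows_for_subjects(fm, split.test_subjects)
            seed = (split.seed * 1000 + si) % (2**31)
            try:
                model = fit_model(spec, train_fm.values, train_fm.labels, seed=seed)
            except ValueError as exc:
                logger.error("rep %d %s: %s; repetition entry skipped", rep, spec.name, exc)
                continue
            models[spec.name] = model
            row = {"rep_index": rep, "modality": spec.modality,
                   "feature_map": spec.feature_map, "kernel": spec.kernel}
            row.update(_evaluate_single(model, test_fm, config.permutation_B,
                                        seed=seed + 1, n_comparisons=len(specs)))
            singles_rows.append(row)
            if rep == 0 and len(np.unique(test_fm.labels)) == 2:
                roc_singles[spec.name] = roc_points(
                    test_fm.labels, predict_proba(model, test_fm.values))
            logger.info("rep %d %s: C=%.4g cv_bacc=%.2f", rep, spec.name,
                        model.c_value, model.cv_balanced_accuracy)
        rep_models.append(models)

    per_rep_singles = pd.DataFrame(singles_rows)
    singles_agg = _aggregate(per_rep_singles, ["modality", "feature_map", "kernel"],
                             config.n_reps)
    best = select_best_per_modality(singles_agg)

    # --- fusion arm: per repetition, fuse that repetition's best models ----
    combos = enumerate_combinations(modality_groups)
    combo_rows: list[dict] = []
    best_channels = {m: (f"{m}-{fmap}" if fmap != m else m) for m, (fmap, _) in best.items()}
    for rep, split in enumerate(splits):
        complete = _complete_visit_matrices(matrices, list(best_channels.values()),
                                            split.test_subjects)
        # re-key by modality for ensemble evaluation
        test_by_mod = {m: complete[ch] for m, ch in best_channels.items()}
        for combo in combos:
            members = []
            for m in combo:
                fmap, kernel = best[m]
                name = ModelSpec(modality=m, feature_map=fmap, kernel=kernel).name
                if name not in rep_models[rep]:
                    members = None
                    break
                members.append(rep_models[rep][name])
            if not members:
                continue
            spec = EnsembleSpec(members=tuple(members))
            rep_metrics = evaluate_ensemble(spec, test_by_mod)
            labels = test_by_mod[combo[0]].labels
            member_probs = np.column_stack([
                predict_proba(mm, test_by_mod[mm.spec.modality].values) for mm in members])
            fused = member_probs @ spec.weights
            perm = permutation_test(labels, (fused >= 0.5).astype(int),
                                    B=config.permutation_B,
                                    seed=(split.seed * 131 + len(combo)) % (2**31),
                                    n_comparisons=len(combos))
            if rep == 0 and len(np.unique(labels)) == 2:
                roc_combos["+".join(combo)] = roc_points(labels, fused)
            row = {"rep_index": rep, "combination": "+".join(combo)}
            row.update(rep_metrics.as_dict())
            row["p_raw"] = perm.p_raw
            row["p_adjusted"] = perm.p_adjusted
            combo_rows.append(row)
    per_rep_combos = pd.DataFrame(combo_rows)
    combos_agg = _aggregate(per_rep_combos, ["combination"], config.n_reps)

    # --- sensitive-biomarker arm on the per-modality best specs -----------
    subset_rows: list[dict] = []
    rank_records: list[dict] = []
    if config.run_selection_arm:
        for rep, split in enumerate(splits):
            for m, (fmap, kernel) in best.items():
                ch = best_channels[m]
                spec = ModelSpec(modality=m, feature_map=fmap, kernel=kernel,
                                 c_search=(specs[0].c_search), cv_folds=specs[0].cv_folds)
                fm = matrices[ch]
                train_fm = _rows_for_subjects(fm, split.train_subjects)
                test_fm = _rows_for_subjects(fm, split.test_subjects)
                seed = (split.seed * 1000 + 500) % (2**31)
                ranking = mrmr_rank(train_fm.values, train_fm.labels,
                                    feature_names=train_fm.feature_names)
                trace = forward_subset_models(
                    spec, train_fm.values, train_fm.labels, ranking, seed=seed,
                    feature_names=train_fm.feature_names, max_k=config.selection_max_k)
                if rep == 0:
                    subset_traces[m] = trace.entries
                chosen = list(ranking.ordered_features[: trace.selected_k])
                model = fit_model(spec, train_fm.subset_features(chosen).values,
                                  train_fm.labels, seed=seed)
                row = {"rep_index": rep, "modality": m, "selected_k": trace.selected_k}
                row.update(_evaluate_single(model, test_fm.subset_features(chosen),
                                            config.permutation_B, seed=seed + 1,
                                            n_comparisons=len(best)))
                subset_rows.append(row)
                for rank_pos, feat in enumerate(ranking.ordered_features, start=1):
                    rank_records.append({"rep_index": rep, "modality": m,
                                         "feature": feat, "rank": rank_pos,
                                         "selected": rank_pos <= trace.selected_k})
                logger.info("rep %d %s selection: k=%d", rep, m, trace.selected_k)
    per_rep_subsets = pd.DataFrame(subset_rows)
    subsets_agg = _aggregate(per_rep_subsets, ["modality"], config.n_reps)

    if rank_records:
        ranks = pd.DataFrame(rank_records)
        importance = (ranks.groupby(["modality", "feature"])
                      .agg(mean_rank=("rank", "mean"),
                           selection_frequency=("selected", "mean"))
                      .reset_index()
                      .sort_values(["modality", "mean_rank"]))
    else:
        importance = pd.DataFrame(columns=["modality", "feature", "mean_rank",
                                           "selection_frequency"])

    report = AggregateReport(
        singles=singles_agg, combinations=combos_agg, subsets=subsets_agg,
        best_per_modality=best, per_rep_singles=per_rep_singles,
        per_rep_combinations=per_rep_combos, per_rep_subsets=per_rep_subsets,
        feature_importance=importance, n_reps=config.n_reps,
        roc_curves_singles=roc_singles, roc_curves_combinations=roc_combos,
        subset_traces=subset_traces,
    )
    if config.out_dir:
        write_report(report, config.out_dir)
    return report


def write_report(report: AggregateReport, out_dir: str | Path) -> None:
    """Write aggregate and per-repetition tables as CSV plus a JSON summary.

    Aggregate table headers carry explicit `_mean`/`_se`/`_sd` suffixes so
    the dispersion convention is visible in the output itself.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.singles.to_csv(out / "single_modality.csv", index=False)
    report.combinations.to_csv(out / "combinations.csv", index=False)
    report.subsets.to_csv(out / "sensitive_subsets.csv", index=False)
    report.per_rep_singles.to_csv(out / "per_rep_single_modality.csv", index=False)
    report.per_rep_combinations.to_csv(out / "per_rep_combinations.csv", index=False)
    report.per_rep_subsets.to_csv(out / "per_rep_sensitive_subsets.csv", index=False)
    report.feature_importance.to_csv(out / "feature_importance.csv", index=False)
    (out / "summary.json").write_text(json.dumps({
        "n_reps": report.n_reps,
        "best_per_modality": {m: list(v) for m, v in report.best_per_modality.items()},
    }, indent=2))
    from . import plots
    if report.roc_curves_singles:
        plots.plot_roc_panel(report.roc_curves_singles, out / "roc_single_modality.png",
                             title="Single-modality ROC (repetition 0)")
    if report.roc_curves_combinations:
        plots.plot_roc_panel(report.roc_curves_combinations, out / "roc_combinations.png",
                             title="Multi-modality ROC (repetition 0)")
    if report.subset_traces:
        plots.plot_accuracy_vs_k(report.subset_traces, out / "accuracy_vs_subset_size.png")
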