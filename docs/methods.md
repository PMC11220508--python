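# Methods

`mcifusion` implements a multimodal prognosis pipeline for mild cognitive
impairment (MCI): given per-visit, atlas-based ROI features from up to four
imaging modalities — structural MRI tissue volumes, AV45 (amyloid) and FDG
(metabolism) PET uptake ratios, and DTI diffusion metrics — it predicts
whether a patient will convert to Alzheimer's disease (cMCI) or remain
stable (sMCI). This note records the models, the synthetic data they are
validated on, and the numerical and design choices that were genuinely
open.

## Feature model

Every modality/feature-map ("channel") contributes one 64-dimensional
vector per visit, one value per region of a 64-ROI anatomical parcellation.
Upstream of the classifier two normalizations are supported:

* **SUVR** — mean PET tracer uptake per ROI divided by the mean uptake of a
  reference region (cerebellum, whole grey matter, whole white matter, or
  pons). SUVR is invariant to global scanner scaling.
* **TIV normalization** — regional tissue volumes divided by total
  intracranial volume (mL/mL), removing head-size differences.

Voxel-level preprocessing (registration, segmentation, smoothing) is out of
scope; the package consumes pre-aggregated ROI tables
(`subject_id, visit_id, label, roi_000..roi_063`).

## Cohort structure and splitting

Subjects carry a binary label and one or more visits; each visit carries a
subset of the modalities. Subjects with at least one visit containing all
required modalities form the **complete-visits set (CVS)**; the rest form
the **incomplete-visits set (IVS)**. Because the late-fusion ensemble can
only be scored on visits where every member modality is present, test
subjects come exclusively from the CVS: each repetition trains on all IVS
subjects plus a random 30% of CVS subjects and tests on the remaining 70%
of the CVS. The draw is stratified by class (not strictly implied by the
design, but it guarantees both classes in the small test set) and the split
is **by participant**: all visits of a test subject are test samples. The
experiment repeats the split 30 times (default) with seeds
`base_seed + rep_index` and reports the mean of per-repetition metrics.

## Per-modality classifier

One support-vector machine per channel and kernel (linear and RBF):

* **Normalization.** Features are z-scored with training-set means/SDs;
  held-out data always reuse the training statistics. Constant features
  get SD clamped to 1 (they become all-zero after centering). Inside
  cross-validation the same rule applies per fold — validation folds never
  contribute to the normalizer.
* **Kernel bandwidth.** `gamma = 1 / (n_features * var)` with `var` the
  pooled variance of all entries of the (normalized) training matrix — the
  'scale' heuristic. On z-scored 64-feature input this is ≈ 1/64.
* **Penalty search.** C is tuned on a log-uniform range [1e-3, 1e3]
  (50 trials by default) by a seeded sequential search: the first half of
  the trials explores log-uniformly, the remainder samples log-normally
  around the running best with a shrinking window. Each candidate is scored
  by stratified 10-fold CV balanced accuracy; ties resolve to the smaller C
  (stronger regularization). The search is deterministic given the seed.
* **Class imbalance.** Misclassification penalties are weighted inversely
  to class frequency (`class_weight="balanced"`).
* **Probabilities.** A Platt-style logistic map `p = σ(a·s + b)` is fitted
  on training-set decision scores (no internal CV; documented as the
  simpler of the two standard options — the monotone map leaves AUC
  unchanged and only the 0.5-threshold crossing matters downstream).
* **Final refit** uses all training data, with gamma recomputed on the full
  normalized training matrix.

Models serialize to versioned JSON (spec, C, gamma, normalizer vectors,
calibration, support vectors) — no binary pickles.

## Late fusion

The ensemble probability for case *i* is the convex combination
`Y_i = Σ_k c_k · y_ki` of member probabilities with `Σ c_k = 1`. Weights
are equal across modalities (each model is an equally trusted expert);
arbitrary weights are accepted by the API but excluded from replication
reports. All subsets of size ≥ 2 of the four modalities are evaluated —
6 pairs, 4 triples, 1 quadruple = 11 combinations. Fused probabilities at
exactly the 0.5 threshold predict cMCI (deterministic; favors sensitivity
in a screening context; configurable). Member models are the per-modality
best performers by mean balanced accuracy across repetitions, refitted
within each repetition on that repetition's training split.

## Sensitive-biomarker selection

Per repetition, on training data only:

1. **mRMR ranking.** Greedy; step 1 maximizes relevance (one-way F
   statistic of feature vs. class), later steps maximize
   relevance / mean |Pearson r| with already-selected features (quotient
   form). The redundancy denominator is floored at 0.01 to avoid blow-ups
   for near-orthogonal candidates. Ties take the lower feature index.
2. **Forward construction.** For k = 1..64 the model uses the top-k ranked
   features, re-running the C search with 10-fold CV per subset.
3. **BIC selection.** `BIC(k) = n·ln(L²/n) + k·ln(n)` with
   `L = 100 − CV balanced accuracy` (natural log; L floored at 0.1 accuracy
   points so a perfect fit stays finite). The subset minimizing BIC wins;
   ties break toward the smaller k.

Reported feature importance is the mean rank across repetitions plus the
selection frequency.

## Metrics and significance

Sensitivity, specificity, balanced accuracy (their mean — the headline
metric), PPV and NPV on the percent scale; F1 and AUC as fractions. Ratios
with zero denominators are reported as NaN with a warning, never silently
zero (reachable in the degenerate low-sensitivity fusion regimes). AUC uses
the Mann–Whitney formulation (ties count ½). Significance of a fixed
decision rule on the test set comes from permuting test labels B = 1000
times (no retraining) with the add-one estimator
`p = (1 + #{perm ≥ obs})/(B + 1)`, Bonferroni-corrected over the family of
models evaluated in the same experiment block. Mean p-values across
repetitions are reported both raw and adjusted.

## Synthetic cohort generator

Real conversion cohorts of this design are access-restricted, so validation
uses a generator that emulates the statistical structure the pipeline
assumes. Per subject *s* with label `z_s ∈ {0,1}`: a shared severity factor
`g_s` and per-modality factors `u_{s,m} = √ρ·g_s + √(1−ρ)·e_{s,m}` (all
standard normal), so `corr(u_m, u_m') = ρ` — the **redundancy** knob.
Planted ROI *j* of channel *c* at a visit takes

    x = √(1−λ²)·ε + d_c·z_s + λ·u_{s,m},   λ = 0.5,

non-planted ROIs take only the noise term `√(1−λ²)·ε`, with ε i.i.d.
standard normal per visit and ROI. The √(1−λ²) scaling keeps the
planted-feature noise variance (visit noise plus severity factor) at
exactly 1 for every ρ, so the empirical
standardized group difference converges to the configured effect size
`d_c`. Visits share `z_s` and `u_{s,m}` — the subject-level dependence that
makes participant-wise splitting necessary.

Defaults mirror the published cohort scale: 486 subjects, 234 converters,
19% complete subjects, 2 visits each. Complete subjects carry all
modalities at every visit; incomplete subjects drop each modality per visit
independently at rate 0.6, forced to keep ≥ 1 modality and ≥ 1 gap (so the
CVS share equals `frac_complete` exactly). The 0.6 rate puts ≈ 74% of
pooled visit-modality samples on the training side at the default split,
matching the published overall share. Default per-channel effect sizes
follow the qualitative informativeness ordering of the modalities (amyloid
PET strongest, GM volumetry and FDG intermediate, WM and DTI weak).

What the generator does **not** emulate: real SUVR/volume measurement
units, spatial correlation between neighboring ROIs, longitudinal
progression within subjects, site/scanner effects, and label noise.
Passing tests therefore demonstrate correctness of the pipeline's
machinery and its qualitative behavior under known signal structure — not
clinical performance on real data.

## Problem sizes used in validation

The test suite and `scripts/acceptance.py` run the pipeline at sizes chosen
to exercise every code path with stable statistics: planted-signal checks
use 400 subjects with d = 1.5 on 10 of 64 ROIs; fusion
complementarity/redundancy checks use two channels with disjoint planted
sets (d = 1.0) over seeds and ρ ∈ {0, ½, 1}; null calibration uses 500
simulated permutation evaluations (B = 199) plus null-cohort model fits;
the C search uses 8–10 trials in these runs. The full 30-repetition,
12-channel experiment is available through `RunConfig`/CLI defaults.

## Known limitations

* The C search is a light sequential optimizer, not a full Bayesian
  treatment; with few trials on near-separable data the chosen C can sit at
  a range boundary.
* With small training sets (e.g. 30% of a 92-subject CVS), the BIC
  criterion favors subsets of ~5–14 features and may recover only part of
  a 10-ROI planted set; recovery is reliable when selection sees the full
  cohort-scale matrix.
* Probability calibration on training scores can be overconfident on
  separable training sets; ranking-based metrics are unaffected.
* Undefined metrics (NaN) propagate into across-repetition means as NaN by
  design for the affected metric only.
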