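"""Tests of the per-modality SVM: gamma heuristic, normalization, C search,
fitting, and probability calibration."""

import numpy as np
import pytest

from mcifusion.metrics import balanced_accuracy
from mcifusion.model import (ModelSpec, TrainedModel, apply_normalizer,
                             compute_gamma, fit_model, fit_normalizer,
                             predict_labels, predict_proba, tune_c)
from mcifusion.splitting import assign_ivs_cvs, make_split


def _blobs(n=60, p=4, sep=4.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    y = np.zeros(n, dtype=int)
    y[n // 2:] = 1
    X[y == 1, 0] += sep
    return X, y


class TestGamma:
    def test_unit_variance_64_features(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((5000, 64))
        X = (X - X.mean()) / X.std()
        assert compute_gamma(64, X) == pytest.approx(1 / 64, abs=1e-9)

    def test_single_feature_unit_variance(self):
        X = np.array([[0.0], [2.0]])  # pooled variance 1
        assert compute_gamma(1, X) == pytest.approx(1.0)

    def test_matches_pooled_variance_oracle(self, rng):
        X = rng.uniform(-3, 5, size=(20, 5))
        flat = X.ravel()
        var_oracle = np.mean(flat**2) - np.mean(flat) ** 2
        assert compute_gamma(5, X) == pytest.approx(1 / (5 * var_oracle), rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            compute_gamma(2, np.ones((4, 2)))

    def test_normalized_input_gamma_near_one_over_p(self, planted_matrix):
        norm = fit_normalizer(planted_matrix.values)
        Xn = apply_normalizer(norm, planted_matrix.values)
        assert compute_gamma(64, Xn) == pytest.approx(1 / 64, abs=1e-6)


class TestNormalizer:
    def test_closed_form_column(self):
        norm = fit_normalizer(np.array([[1.0], [2.0], [3.0]]))
        out = apply_normalizer(norm, np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(out.ravel(), [-1.224744871, 0.0, 1.224744871], atol=1e-8)

    def test_self_application_zero_mean_unit_sd(self, rng):
        X = rng.uniform(-2, 9, size=(40, 6))
        Xn = apply_normalizer(fit_normalizer(X), X)
        np.testing.assert_allclose(Xn.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(Xn.std(axis=0), 1.0, atol=1e-12)

    def test_heldout_uses_train_statistics(self, rng):
        train = rng.standard_normal((30, 3))
        held = rng.standard_normal((10, 3)) + 5.0
        norm = fit_normalizer(train)
        out = apply_normalizer(norm, held)
        np.testing.assert_allclose(out, (held - norm.means) / norm.sds)
        assert np.all(out.mean(axis=0) > 1.0)  # train stats, not held-out stats

    def test_matches_per_column_oracle(self, rng):
        X = rng.uniform(0, 4, size=(25, 4))
        norm = fit_normalizer(X)
        for j in range(4):
            assert norm.means[j] == pytest.approx(X[:, j].mean())
            assert norm.sds[j] == pytest.approx(X[:, j].std())

    def test_constant_feature_clamped(self):
        X = np.column_stack([np.ones(5), np.arange(5.0)])
        norm = fit_normalizer(X)
        out = apply_normalizer(norm, X)
        np.testing.assert_array_equal(out[:, 0], 0.0)


class TestTuneC:
    def test_separable_data_high_cv_accuracy(self):
        X, y = _blobs(sep=6.0)
        spec = ModelSpec(kernel="linear", c_search=(1e-2, 1e2, 4), cv_folds=5)
        _, cv_bacc = tune_c(spec, X, y, seed=0)
        assert cv_bacc >= 95.0

    def test_single_trial_returns_single_candidate(self):
        X, y = _blobs()
        spec = ModelSpec(kernel="rbf", c_search=(1e-3, 1e3, 1), cv_folds=5)
        from mcifusion.model import propose_c_candidates
        expected = propose_c_candidates(spec.c_search, seed=3)
        best_c, _ = tune_c(spec, X, y, seed=3)
        assert best_c == pytest.approx(expected[0])

    def test_explicit_grid_matches_exhaustive_oracle(self):
        # Brute-force every candidate with the same fixed folds and compare.
        from sklearn.model_selection import StratifiedKFold
        from mcifusion.model import _cv_balanced_accuracy
        X, y = _blobs(n=50, sep=1.0, seed=4)
        grid = [0.01, 1.0, 100.0]
        spec = ModelSpec(kernel="rbf", cv_folds=5)
        best_c, best_score = tune_c(spec, X, y, seed=9, candidates=grid)
        folds = StratifiedKFold(n_splits=5, shuffle=True, random_state=9)
        scores = [_cv_balanced_accuracy(spec, X, y, c, folds) for c in grid]
        assert best_score == pytest.approx(max(scores))
        winners = [c for c, s in zip(grid, scores) if s == max(scores)]
        assert best_c == min(winners)  # ties resolve to the smaller C

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).standard_normal((20, 3))
        with pytest.raises(ValueError, match="classes"):
            tune_c(ModelSpec(), X, np.zeros(20, dtype=int))


class TestFitModel:
    def test_refit_identical(self):
        X, y = _blobs(seed=2)
        spec = ModelSpec(kernel="rbf", c_search=(1e-2, 1e2, 5), cv_folds=5)
        a = fit_model(spec, X, y, seed=7)
        b = fit_model(spec, X, y, seed=7)
        assert a.c_value == b.c_value
        np.testing.assert_array_equal(predict_proba(a, X), predict_proba(b, X))

    def test_label_flip_flips_predictions(self):
        X, y = _blobs(n=80, sep=3.0, seed=3)
        spec = ModelSpec(kernel="linear", cv_folds=5)
        a = fit_model(spec, X, y, seed=1, candidates=[1.0])
        b = fit_model(spec, X, 1 - y, seed=1, candidates=[1.0])
        pa = predict_labels(a, X)
        pb = predict_labels(b, X)
        # Balanced class weighting makes the decision rule symmetric under
        # label exchange (up to boundary ties).
        assert np.mean(pa == 1 - pb) > 0.95

    def test_planted_effect_test_accuracy(self, planted_cohort, planted_matrix):
        ivs_cvs = assign_ivs_cvs(planted_cohort, ["m1"])
        plan = make_split(planted_cohort, ivs_cvs, 0, base_seed=1)
        tr = np.isin(planted_matrix.subject_ids.astype(str), sorted(plan.train_subjects))
        spec = ModelSpec(kernel="rbf", c_search=(1e-3, 1e3, 10), cv_folds=10)
        model = fit_model(spec, planted_matrix.values[tr], planted_matrix.labels[tr], seed=1)
        bacc = balanced_accuracy(planted_matrix.labels[~tr],
                                 predict_labels(model, planted_matrix.values[~tr]))
        assert bacc > 80.0


@pytest.fixture(scope="module")
def model():
    X, y = _blobs(n=80, sep=2.0, seed=5)
    return fit_model(ModelSpec(kernel="linear", cv_folds=5), X, y,
                     seed=2, candidates=[1.0])


class TestPredictProba:

    def test_probabilities_in_open_interval(self, model):
        X, _ = _blobs(n=80, sep=2.0, seed=5)
        p = predict_proba(model, X)
        assert np.all(p > 0) and np.all(p < 1)

    def test_boundary_score_maps_to_calibration_midpoint(self, model):
        a, b = model.calibration
        midpoint = 1 / (1 + np.exp(-b))
        from mcifusion.model import decision_scores
        X, _ = _blobs(n=80, sep=2.0, seed=5)
        s = decision_scores(model, X)
        p = predict_proba(model, X)
        j = np.argmin(np.abs(s))
        assert p[j] == pytest.approx(1 / (1 + np.exp(-(a * s[j] + b))))
        assert 1 / (1 + np.exp(-(a * 0 + b))) == pytest.approx(midpoint)

    def test_monotone_in_decision_score(self, model):
        from mcifusion.model import decision_scores
        X, _ = _blobs(n=80, sep=2.0, seed=5)
        s = decision_scores(model, X)
        p = predict_proba(model, X)
        order = np.argsort(s)
        assert np.all(np.diff(p[order]) >= 0)

    def test_matches_logistic_closed_form(self, model):
        from mcifusion.model import decision_scores
        X, _ = _blobs(n=80, sep=2.0, seed=5)
        s = decision_scores(model, X)
        a, b = model.calibration
        np.testing.assert_allclose(predict_proba(model, X), 1 / (1 + np.exp(-(a * s + b))))

    def test_dimension_mismatch_rejected(self, model):
        with pytest.raises(ValueError, match="mismatch"):
            predict_proba(model, np.zeros((3, 9)))


class TestSerialization:
    def test_json_round_trip_predictions(self):
        X, y = _blobs(n=60, sep=2.0, seed=8)
        for kernel in ("linear", "rbf"):
            model = fit_model(ModelSpec(kernel=kernel, cv_folds=5), X, y,
                              seed=4, candidates=[2.0])
            back = TrainedModel.from_json(model.to_json())
            np.testing.assert_allclose(predict_proba(back, X), predict_proba(model, X),
                                       atol=1e-10)


class TestLeakageGuard:
    def test_fold_normalization_uses_train_fold_statistics(self):
        """Reproduce one CV fold by hand and confirm the validation part is
        transformed with the train fold's means/sds, not its own."""
        from sklearn.model_selection import StratifiedKFold
        from sklearn.svm import SVC
        from mcifusion.model import _cv_balanced_accuracy
        X, y = _blobs(n=40, sep=1.5, seed=6)
        spec = ModelSpec(kernel="rbf", cv_folds=4)
        folds = StratifiedKFold(n_splits=4, shuffle=True, random_state=11)
        got = _cv_balanced_accuracy(spec, X, y, 1.0, folds)
        scores = []
        for tr_idx, va_idx in folds.split(X, y):
            mu, sd = X[tr_idx].mean(axis=0), X[tr_idx].std(axis=0)
            sd = np.where(sd == 0, 1.0, sd)
            Xtr, Xva = (X[tr_idx] - mu) / sd, (X[va_idx] - mu) / sd
            gamma = 1 / (Xtr.shape[1] * Xtr.var())
            clf = SVC(C=1.0, kernel="rbf", gamma=gamma, class_weight="balanced")
            clf.fit(Xtr, y[tr_idx])
            scores.append(balanced_accuracy(y[va_idx], clf.predict(Xva)))
        assert got == pytest.approx(np.mean(scores))
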