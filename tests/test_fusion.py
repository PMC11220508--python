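"""Tests of equal-weight probability fusion and combination enumeration."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from mcifusion.fusion import (EnsembleSpec, enumerate_combinations,
                              equal_weights, evaluate_ensemble, fuse_probabilities)
from mcifusion.io import FeatureMatrix
from mcifusion.model import ModelSpec, fit_model
from mcifusion.synthetic import cohort_to_feature_matrices


class TestFuseProbabilities:
    def test_equal_weight_pair(self):
        out = fuse_probabilities(np.array([[0.8, 0.6]]), [0.5, 0.5])
        assert out[0] == pytest.approx(0.7)

    def test_degenerate_weight_reproduces_member(self, rng):
        P = rng.random((10, 2))
        np.testing.assert_allclose(fuse_probabilities(P, [1.0, 0.0]), P[:, 0])

    def test_identical_members_idempotent(self, rng):
        p = rng.random(10)
        P = np.column_stack([p, p, p])
        np.testing.assert_allclose(fuse_probabilities(P, equal_weights(3)), p)

    def test_bad_weight_sum_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            fuse_probabilities(np.ones((2, 2)) * 0.5, [0.5, 0.6])

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="weights"):
            fuse_probabilities(np.ones((2, 3)) * 0.5, [0.5, 0.5])

    @given(P=arrays(float, (7, 3), elements=st.floats(0, 1)),
           raw=arrays(float, 3, elements=st.floats(0.01, 1)))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_convex_combination_bounds_and_permutation_invariance(self, P, raw):
        w = raw / raw.sum()
        if abs(w.sum() - 1) > 1e-12:
            w[-1] += 1.0 - w.sum()
        out = fuse_probabilities(P, w)
        assert np.all(out >= P.min(axis=1) - 1e-12)
        assert np.all(out <= P.max(axis=1) + 1e-12)
        # equal-weight fusion is invariant under member reordering
        eq = equal_weights(3)
        perm = np.array([2, 0, 1])
        np.testing.assert_allclose(fuse_probabilities(P, eq),
                                   fuse_probabilities(P[:, perm], eq), atol=1e-12)


class TestEnumerateCombinations:
    def test_four_modalities_give_eleven(self):
        combos = enumerate_combinations(["smri", "av45", "fdg", "dti"])
        assert len(combos) == 11
        assert sum(len(c) == 2 for c in combos) == 6
        assert sum(len(c) == 3 for c in combos) == 4
        assert sum(len(c) == 4 for c in combos) == 1

    def test_two_modalities_single_pair(self):
        assert enumerate_combinations(["a", "b"]) == [("a", "b")]

    def test_five_modalities_match_brute_force(self):
        mods = ["a", "b", "c", "d", "e"]
        combos = enumerate_combinations(mods)
        brute = [tuple(s) for k in range(2, 6) for s in itertools.combinations(mods, k)]
        assert combos == brute
        assert len(combos) == 2**5 - 5 - 1

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            enumerate_combinations(["a", "a", "b"])


def _toy_members(seed=0):
    rng = np.random.default_rng(seed)
    models = []
    for i, mod in enumerate(("a", "b")):
        X = rng.standard_normal((40, 3))
        y = np.array([0] * 20 + [1] * 20)
        X[y == 1, 0] += 3.0
        models.append(fit_model(ModelSpec(modality=mod, feature_map=mod, kernel="linear",
                                          cv_folds=4), X, y, seed=i, candidates=[1.0]))
    return tuple(models)


def _fm(values, labels, mod, sids=None):
    n = len(labels)
    return FeatureMatrix(
        values=values, feature_names=[f"roi_{j:03d}" for j in range(values.shape[1])],
        labels=np.asarray(labels), subject_ids=np.array([f"S{i}" for i in range(n)]),
        visit_ids=np.array(["V0"] * n), modality=mod, feature_map=mod)


class TestEvaluateEnsemble:
    def test_identical_members_match_single(self, rng):
        m1, _ = _toy_members()
        m2 = m1  # same trained model under a different modality name
        from dataclasses import replace
        m2 = replace(m1, spec=ModelSpec(modality="b", feature_map="b", kernel="linear",
                                        cv_folds=4))
        X = rng.standard_normal((20, 3))
        y = np.array([0, 1] * 10)
        spec = EnsembleSpec(members=(m1, m2))
        rep = evaluate_ensemble(spec, {"a": _fm(X, y, "a"), "b": _fm(X, y, "b")})
        from mcifusion.model import predict_proba
        from mcifusion.metrics import confusion, metric_suite, roc_auc
        probs = predict_proba(m1, X)
        single = metric_suite(confusion(y, (probs >= 0.5).astype(int)), auc=roc_auc(y, probs))
        assert rep.balanced_accuracy == pytest.approx(single.balanced_accuracy)
        assert rep.auc == pytest.approx(single.auc)

    def test_perfect_plus_antiperfect_all_ties_predict_positive(self):
        # Members whose probabilities are p and 1-p fuse to exactly 0.5
        # everywhere; the tie rule predicts cMCI, so sensitivity is 100 and
        # specificity 0.  Dyadic probabilities keep the fusion arithmetic
        # exact.
        from mcifusion.metrics import confusion, metric_suite
        p = np.array([1, 3, 5, 7, 9, 11, 13, 15]) / 16.0
        P = np.column_stack([p, 1.0 - p])
        fused = fuse_probabilities(P, equal_weights(2))
        np.testing.assert_array_equal(fused, 0.5)
        y = np.array([0, 1] * 4)
        preds = (fused >= 0.5).astype(int)  # ties predict positive
        rep = metric_suite(confusion(y, preds))
        assert rep.sensitivity == pytest.approx(100.0)
        assert rep.specificity == pytest.approx(0.0)

    def test_misaligned_visits_identified(self, rng):
        m1, m2 = _toy_members()
        X = rng.standard_normal((10, 3))
        y = np.array([0, 1] * 5)
        fm_a = _fm(X, y, "a")
        fm_b = _fm(X[:9], y[:9], "b")
        with pytest.raises(ValueError, match="misaligned"):
            evaluate_ensemble(EnsembleSpec(members=(m1, m2)), {"a": fm_a, "b": fm_b})

    def test_missing_member_modality_rejected(self, rng):
        m1, m2 = _toy_members()
        X = rng.standard_normal((10, 3))
        y = np.array([0, 1] * 5)
        with pytest.raises(ValueError, match="no test matrix"):
            evaluate_ensemble(EnsembleSpec(members=(m1, m2)), {"a": _fm(X, y, "a")})

    def test_duplicate_member_modalities_rejected(self):
        m1, _ = _toy_members()
        with pytest.raises(ValueError, match="distinct"):
            EnsembleSpec(members=(m1, m1))
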