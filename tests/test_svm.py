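"""SVM dual solver against closed-form and quadratic-programming oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from striaekit.svm import (
    ABLATION_SUBSETS,
    BinaryLinearSVM,
    OneVsRestSVM,
    ablation_study,
    evaluate,
    solve_dual_qp,
    stratified_split,
)


def _separable_problem(rng, n, d=2, margin=1.5):
    X = rng.normal(0, 1, (n, d))
    y = np.where(X[:, 0] + 0.5 * X[:, -1] > 0, 1.0, -1.0)
    X[:, 0] += y * margin
    return X, y


class TestBinarySvm:
    def test_two_point_closed_form(self):
        X = np.array([[-1.0], [1.0]])
        y = np.array([-1.0, 1.0])
        m = BinaryLinearSVM(reg_bound=100.0).fit(X, y)
        assert m.w == pytest.approx([1.0], abs=1e-8)
        assert m.b == pytest.approx(0.0, abs=1e-8)
        # both points are support vectors exactly on the margin
        assert list(m.support_) == [0, 1]
        assert y * m.decision_function(X) == pytest.approx([1.0, 1.0], abs=1e-8)

    @pytest.mark.parametrize("trial", range(5))
    @pytest.mark.parametrize("reg_bound", [1.0, 10.0, 100.0])
    def test_matches_qp_oracle_on_small_problems(self, trial, reg_bound):
        rng = np.random.default_rng(100 + trial)
        X, y = _separable_problem(rng, int(rng.integers(4, 9)))
        if len(set(y)) < 2:
            pytest.skip("degenerate draw")
        w_ref, b_ref = solve_dual_qp(X, y, C=reg_bound)
        m = BinaryLinearSVM(reg_bound=reg_bound).fit(X, y)
        assert m.w == pytest.approx(w_ref, abs=1e-4)
        assert m.b == pytest.approx(b_ref, abs=1e-4)

    def test_dual_feasibility(self, rng):
        X, y = _separable_problem(rng, 30)
        m = BinaryLinearSVM(reg_bound=1.0).fit(X, y)
        assert abs(np.sum(m.alpha * y)) < 1e-8
        assert (m.alpha >= 0).all() and (m.alpha <= 1.0).all()

    def test_hard_margin_constraint_satisfied(self, rng):
        X, y = _separable_problem(rng, 20, margin=2.0)
        m = BinaryLinearSVM(reg_bound=1e4).fit(X, y)
        assert (y * m.decision_function(X) >= 1.0 - 1e-6).all()

    def test_scaling_leaves_predictions_unchanged(self, rng):
        X, y = _separable_problem(rng, 12)
        queries = rng.normal(0, 2, (40, 2))
        m1 = BinaryLinearSVM(reg_bound=1e4).fit(X, y)
        c = 3.7
        m2 = BinaryLinearSVM(reg_bound=1e4).fit(c * X, y)
        assert np.array_equal(
            np.sign(m1.decision_function(queries)),
            np.sign(m2.decision_function(c * queries)),
        )
        # the weight vector scales inversely so w.x is invariant
        assert m2.w == pytest.approx(m1.w / c, rel=1e-3)

    def test_rejects_single_class(self):
        with pytest.raises(ValueError):
            BinaryLinearSVM().fit(np.zeros((3, 2)), np.ones(3))


class TestOneVsRest:
    def test_separable_blobs_perfect_training_accuracy(self, rng):
        centers = {"mild": (-4, 0), "moderate": (0, 4), "severe": (4, 0)}
        X = np.vstack([rng.normal(c, 0.3, (15, 2)) for c in centers.values()])
        labels = np.repeat(list(centers), 15)
        model = OneVsRestSVM(reg_bound=100.0).fit(X, labels)
        assert (model.predict(X) == labels).all()

    def test_tie_break_uses_class_order(self):
        model = OneVsRestSVM(standardize=False)
        model.fit(
            np.array([[0.0, 1.0], [1.0, 0.0], [0.5, 0.5], [1.0, 1.0], [0.0, 0.0], [0.7, 0.2]]),
            ["mild", "moderate", "severe", "mild", "moderate", "severe"],
        )
        for cls in model.classes_:  # force identical decision values
            model.machines_[cls].w = np.zeros(2)
            model.machines_[cls].b = 0.0
        assert model.predict([[0.3, 0.3]])[0] == "mild"

    def test_arity_mismatch_rejected(self, rng):
        X, y = _separable_problem(rng, 10)
        model = OneVsRestSVM().fit(X, np.where(y > 0, "severe", "mild"))
        with pytest.raises(ValueError, match="arity"):
            model.predict(np.zeros((2, 3)))

    def test_json_roundtrip_preserves_predictions(self, rng, tmp_path):
        X, y = _separable_problem(rng, 20)
        labels = np.where(y > 0, "severe", "mild")
        model = OneVsRestSVM(feature_subset=("C", "D")).fit(X, labels)
        path = tmp_path / "model.json"
        model.to_json(path)
        clone = OneVsRestSVM.from_json(path)
        queries = rng.normal(0, 2, (30, 2))
        assert np.array_equal(model.predict(queries), clone.predict(queries))


class TestStratifiedSplit:
    def test_published_split_design(self):
        labels = np.repeat(["mild", "moderate", "severe"], [80, 76, 86])
        train, test = stratified_split(labels, 0.8, seed=0)
        tr, te = pd.Series(labels[train]).value_counts(), pd.Series(labels[test]).value_counts()
        assert (tr["mild"], tr["moderate"], tr["severe"]) == (64, 61, 69)
        assert (te["mild"], te["moderate"], te["severe"]) == (16, 15, 17)

    def test_exact_fraction(self):
        labels = ["mild"] * 10
        labels[0] = "severe"  # need two classes? no - single class per call is fine
        labels = np.array(["mild"] * 10)
        train, test = stratified_split(labels, 0.8, seed=1)
        assert (len(train), len(test)) == (8, 2)

    def test_deterministic_under_seed(self):
        labels = np.repeat(["mild", "severe"], [20, 20])
        s1 = stratified_split(labels, 0.8, seed=7)
        s2 = stratified_split(labels, 0.8, seed=7)
        assert np.array_equal(s1[0], s2[0]) and np.array_equal(s1[1], s2[1])

    def test_partition_is_disjoint_and_complete(self):
        labels = np.repeat(["mild", "moderate", "severe"], [9, 11, 13])
        train, test = stratified_split(labels, 0.8, seed=3)
        assert len(set(train) & set(test)) == 0
        assert len(train) + len(test) == len(labels)

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            stratified_split(np.array(["mild", "severe", "severe"]), 0.8, seed=0)


class TestEvaluate:
    def _model(self, rng):
        X, y = _separable_problem(rng, 20)
        return OneVsRestSVM().fit(X, np.where(y > 0, "severe", "mild")), X, y

    def test_rate_arithmetic(self, rng):
        model, X, y = self._model(rng)
        labels = np.where(y > 0, "severe", "mild").copy()
        pred = model.predict(X)
        correct = int((pred == labels).sum())
        rep = evaluate(model, X, labels)
        assert rep.recognition_rate == round(100 * correct / len(labels), 2)

    def test_perfect_predictions(self, rng):
        model, X, y = self._model(rng)
        rep = evaluate(model, X, np.where(y > 0, "severe", "mild"))
        assert rep.recognition_rate == 100.0

    def test_disjoint_label_sets_scores_zero(self, rng):
        model, X, y = self._model(rng)
        rep = evaluate(model, X, np.array(["moderate"] * len(y)))
        assert rep.recognition_rate == 0.0

    def test_empty_test_set_rejected(self, rng):
        model, X, y = self._model(rng)
        with pytest.raises(ValueError):
            evaluate(model, X[:0], np.array([]))


class TestAblation:
    def test_five_standard_subsets(self, small_cohort_features):
        summary, details = ablation_study(small_cohort_features, n_repeats=2, seed=0)
        assert len(summary) == 5
        assert list(summary["subset"]) == ["+".join(s) for s in ABLATION_SUBSETS]
        assert all(len(v) == 2 for v in details.values())

    def test_reproducible_under_seed(self, small_cohort_features):
        s1, _ = ablation_study(small_cohort_features, n_repeats=2, seed=9)
        s2, _ = ablation_study(small_cohort_features, n_repeats=2, seed=9)
        pd.testing.assert_frame_equal(s1, s2)

    def test_missing_feature_rejected(self, small_cohort_features):
        with pytest.raises(ValueError, match="missing features"):
            ablation_study(small_cohort_features, subsets=[("C", "Z")], n_repeats=1)

    def test_rows_without_elasticity_refused(self, small_cohort_features):
        df = small_cohort_features.copy()
        df.loc[df.index[0], "E"] = np.nan
        with pytest.raises(ValueError, match="lack values"):
            ablation_study(df, subsets=[("C", "D", "W", "A", "E")], n_repeats=1)
        # subsets that do not touch E still run
        summary, _ = ablation_study(df, subsets=[("C", "D")], n_repeats=1, seed=0)
        assert len(summary) == 1
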