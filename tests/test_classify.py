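"""Splitting protocol, classifiers, confusion matrices, macro metrics, ROC."""

import numpy as np
import pytest

from otodx.classify import (
    EvaluationError,
    ModelSpec,
    confusion_matrix,
    labels_to_indicator,
    macro_metrics,
    macro_roc,
    repeated_evaluation,
    stratified_split,
    train_model,
)


def make_labels(n_per_class, classes=("a", "b", "c", "d")):
    return np.repeat(classes, n_per_class)


class TestStratifiedSplit:
    def test_reference_720_image_split_gives_576_and_144(self):
        labels = make_labels(180)
        split = stratified_split(labels, seed=0)
        assert len(split.train_indices) == 576
        assert len(split.validation_indices) == 144
        for c in "abcd":
            assert (labels[split.train_indices] == c).sum() == 144
            assert (labels[split.validation_indices] == c).sum() == 36
        assert not set(split.train_indices) & set(split.validation_indices)

    def test_all_train_fraction(self):
        split = stratified_split(make_labels(5), fractions=(1.0, 0.0), seed=1)
        assert len(split.train_indices) == 20 and len(split.validation_indices) == 0

    def test_same_seed_reproduces_split(self):
        labels = make_labels(30)
        s1 = stratified_split(labels, seed=9)
        s2 = stratified_split(labels, seed=9)
        assert np.array_equal(s1.train_indices, s2.train_indices)
        assert not np.array_equal(
            stratified_split(labels, seed=10).train_indices, s1.train_indices
        )

    def test_largest_remainder_rounding_on_unbalanced_classes(self):
        labels = np.array(["a"] * 7 + ["b"] * 13)
        split = stratified_split(labels, seed=2)
        # 0.8*20 = 16 train total; quotas 5.6 and 10.4 -> 6 and 10
        assert (labels[split.train_indices] == "a").sum() == 6
        assert (labels[split.train_indices] == "b").sum() == 10

    def test_tiny_class_rejected(self):
        with pytest.raises(EvaluationError):
            stratified_split(np.array(["a", "b", "b"]), seed=0)


class TestTrainModel:
    def test_linear_svm_separates_separable_clouds(self, rng):
        X = np.vstack([rng.normal(0, 1, (30, 3)), rng.normal(10, 1, (30, 3))])
        y = np.array(["neg"] * 30 + ["pos"] * 30)
        model = train_model(X, y, ModelSpec("svm", {"kernel": "linear"}))
        assert (model.predict(X) == y).all()

    def test_1nn_memorizes_distinct_training_points(self, rng):
        X = rng.normal(size=(40, 5))
        y = np.array(["a", "b", "c", "d"] * 10)
        model = train_model(X, y, ModelSpec("knn", {"n_neighbors": 1}))
        assert (model.predict(X) == y).all()

    def test_tree_reproduces_pure_binary_partition(self):
        X = np.array([[0.0], [0.0], [1.0], [1.0]])
        y = np.array(["no", "no", "yes", "yes"])
        model = train_model(X, y, ModelSpec("tree"))
        assert (model.predict(X) == y).all()

    def test_invalid_inputs_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        with pytest.raises(EvaluationError):
            train_model(X, np.array(["a"] * 10), ModelSpec("svm"))
        X[0, 0] = np.nan
        with pytest.raises(EvaluationError):
            train_model(X, np.array(["a"] * 5 + ["b"] * 5), ModelSpec("svm"))

    def test_score_matrix_has_one_column_per_class(self, rng):
        X = np.vstack([rng.normal(i * 5, 1, (20, 2)) for i in range(4)])
        y = make_labels(20)
        for kind in ("svm", "knn", "tree"):
            model = train_model(X, y, ModelSpec(kind))
            assert model.score_matrix(X).shape == (80, 4)


class TestConfusionMatrix:
    def test_perfect_prediction_is_diagonal(self):
        y = make_labels(40)
        cm = confusion_matrix(y, y, ["a", "b", "c", "d"])
        assert np.array_equal(cm.counts, np.diag([40, 40, 40, 40]))

    def test_counts_match_brute_force_pair_tally(self, rng):
        classes = ["a", "b", "c"]
        actual = rng.choice(classes, 200)
        predicted = rng.choice(classes, 200)
        cm = confusion_matrix(actual, predicted, classes)
        for i, a in enumerate(classes):
            for j, p in enumerate(classes):
                assert cm.counts[i, j] == ((actual == a) & (predicted == p)).sum()

    def test_empty_input_warns_and_returns_zeros(self):
        with pytest.warns(UserWarning):
            cm = confusion_matrix([], [], ["a", "b"])
        assert cm.counts.sum() == 0

    def test_unknown_label_rejected(self):
        with pytest.raises(EvaluationError):
            confusion_matrix(["a"], ["z"], ["a", "b"])


class TestMacroMetrics:
    def test_diagonal_matrix_scores_one_everywhere(self):
        cm = confusion_matrix(make_labels(10), make_labels(10), ["a", "b", "c", "d"])
        m = macro_metrics(cm)
        assert m.accuracy == m.sensitivity == m.specificity == m.ppv == 1.0

    def test_two_class_hand_computed_decomposition(self):
        # cm = [[30, 10], [5, 55]]: per-class binary metrics averaged
        actual = ["a"] * 40 + ["b"] * 60
        predicted = ["a"] * 30 + ["b"] * 10 + ["a"] * 5 + ["b"] * 55
        m = macro_metrics(confusion_matrix(actual, predicted, ["a", "b"]))
        assert m.sensitivity == pytest.approx(np.mean([30 / 40, 55 / 60]))
        assert m.specificity == pytest.approx(np.mean([55 / 60, 30 / 40]))
        assert m.ppv == pytest.approx(np.mean([30 / 35, 55 / 65]))
        assert m.accuracy == pytest.approx((30 + 55) / 100)

    def test_uniform_random_predictions_approach_analytic_expectations(self):
        rng = np.random.default_rng(5)
        classes = ["a", "b", "c", "d"]
        actual = rng.choice(classes, 10_000)
        predicted = rng.choice(classes, 10_000)
        m = macro_metrics(confusion_matrix(actual, predicted, classes))
        assert m.sensitivity == pytest.approx(0.25, abs=0.02)
        assert m.specificity == pytest.approx(0.75, abs=0.02)

    def test_degenerate_class_contributes_zero_and_is_flagged(self):
        # class "c" absent from the evaluated sample
        m = macro_metrics(confusion_matrix(["a", "b"], ["a", "b"], ["a", "b", "c"]))
        assert "c" in m.degenerate_classes
        assert m.sensitivity == pytest.approx((1 + 1 + 0) / 3)

    def test_agrees_with_one_vs_rest_oracle_on_random_matrices(self, rng):
        from otodx.classify import ConfusionMatrix

        for _ in range(200):
            counts = rng.integers(0, 20, size=(4, 4))
            if counts.sum() == 0:
                continue
            cm = ConfusionMatrix(counts=counts, class_order=list("abcd"))
            m = macro_metrics(cm)
            n = counts.sum()
            accs, senss, specs, ppvs = [], [], [], []
            for i in range(4):
                tp = counts[i, i]
                fn = counts[i].sum() - tp
                fp = counts[:, i].sum() - tp
                tn = n - tp - fn - fp
                accs.append((tp + tn) / n)
                senss.append(tp / (tp + fn) if tp + fn else 0.0)
                specs.append(tn / (tn + fp) if tn + fp else 0.0)
                ppvs.append(tp / (tp + fp) if tp + fp else 0.0)
            assert m.accuracy == pytest.approx(np.mean(accs))
            assert m.sensitivity == pytest.approx(np.mean(senss))
            assert m.specificity == pytest.approx(np.mean(specs))
            assert m.ppv == pytest.approx(np.mean(ppvs))


class TestMacroROC:
    def test_scores_equal_to_indicator_give_auc_one(self):
        ind = labels_to_indicator(make_labels(10), ["a", "b", "c", "d"])
        _, _, auc = macro_roc(ind, ind.astype(float))
        assert auc == 1.0

    def test_label_independent_scores_give_auc_half(self):
        rng = np.random.default_rng(11)
        ind = labels_to_indicator(rng.choice(list("abcd"), 5000), list("abcd"))
        scores = rng.uniform(size=ind.shape)
        _, _, auc = macro_roc(ind, scores)
        assert auc == pytest.approx(0.5, abs=0.02)

    def test_auc_matches_mann_whitney_estimator(self, rng):
        ind = labels_to_indicator(rng.choice(list("abcd"), 50), list("abcd"))
        scores = rng.normal(size=ind.shape) + ind  # informative but noisy
        _, _, auc = macro_roc(ind, scores)
        y = ind.ravel().astype(bool)
        s = scores.ravel()
        pos, neg = s[y], s[~y]
        wins = sum((p > neg).sum() + 0.5 * (p == neg).sum() for p in pos)
        assert auc == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-9)

    def test_constant_scores_are_degenerate_but_defined(self):
        ind = labels_to_indicator(["a", "b"], ["a", "b"])
        with pytest.warns(UserWarning):
            _, _, auc = macro_roc(ind, np.ones_like(ind, dtype=float))
        assert auc == pytest.approx(0.5)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(EvaluationError):
            macro_roc(np.eye(3, dtype=int), np.zeros((2, 3)))


@pytest.fixture(scope="module")
def clouds():
    """Four well-separated Gaussian clouds (centers 10 sigma apart)."""
    rng = np.random.default_rng(21)
    X = np.vstack([rng.normal(10 * i, 1.0, size=(40, 4)) for i in range(4)])
    y = make_labels(40)
    return X, y


class TestRepeatedEvaluation:
    def test_single_rep_equals_single_split_run(self, clouds):
        X, y = clouds
        spec = ModelSpec("knn")
        result = repeated_evaluation(X, y, spec, n_reps=1, seed=3)
        split = stratified_split(y, seed=3)
        model = train_model(X[split.train_indices], y[split.train_indices], ModelSpec("knn", seed=3))
        manual = (model.predict(X[split.validation_indices]) == y[split.validation_indices]).mean()
        # for a perfect or near-perfect classifier, accuracy matches directly
        assert result.per_rep[0].sensitivity == pytest.approx(manual, abs=0.05)

    def test_same_master_seed_reproduces_summary(self, clouds):
        X, y = clouds
        spec = ModelSpec("svm")
        r1 = repeated_evaluation(X, y, spec, n_reps=3, seed=7)
        r2 = repeated_evaluation(X, y, spec, n_reps=3, seed=7)
        assert r1.mean == r2.mean and r1.std == r2.std

    def test_separable_clouds_reach_high_accuracy(self, clouds):
        X, y = clouds
        result = repeated_evaluation(X, y, ModelSpec("svm"), n_reps=5, seed=0)
        assert result.mean["accuracy"] >= 0.99

    def test_fixed_test_set_reports_per_rep_mean_and_vote(self, clouds):
        X, y = clouds
        rng = np.random.default_rng(33)
        Xt = np.vstack([rng.normal(10 * i, 1.0, size=(10, 4)) for i in range(4)])
        yt = make_labels(10)
        result = repeated_evaluation(
            X, y, ModelSpec("svm"), n_reps=3, seed=1, test_features=Xt, test_labels=yt
        )
        assert result.test_mean is not None and result.test_mean["accuracy"] >= 0.99
        assert result.test_vote.accuracy >= 0.99


from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp


@settings(max_examples=50, deadline=None, derandomize=True)
@given(counts=hnp.arrays(np.int64, (4, 4), elements=st.integers(0, 50)))
def test_macro_metrics_bounded_and_perfect_iff_diagonal(counts):
    from otodx.classify import ConfusionMatrix

    if counts.sum() == 0:
        return
    m = macro_metrics(ConfusionMatrix(counts=counts, class_order=list("abcd")))
    for v in (m.accuracy, m.sensitivity, m.specificity, m.ppv):
        assert 0.0 <= v <= 1.0
    off_diagonal = counts.sum() - np.trace(counts)
    if off_diagonal == 0 and np.all(np.diag(counts) > 0):
        assert m.accuracy == m.sensitivity == m.specificity == m.ppv == 1.0
    if off_diagonal > 0:
        assert m.accuracy < 1.0
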