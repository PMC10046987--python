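"""Classifier registry, confusion metrics, AUC and cross-validation."""

import itertools

import numpy as np
import pytest
from oracles import pair_count_auc

from iristex.errors import StratificationError, UndefinedAUCError
from iristex.evaluation import (
    ConfusionMatrix,
    classifier_registry,
    confusion,
    metrics_from_confusion,
    roc_auc,
    stratified_kfold_eval,
)


class TestRegistry:
    def test_exactly_22_presets_in_5_families(self):
        reg = classifier_registry()
        assert len(reg) == 22
        families = {c.family for c in reg}
        assert families == {"decision_tree", "naive_bayes", "svm", "knn", "neural_network"}
        by_family = {f: sum(c.family == f for c in reg) for f in families}
        assert by_family == {
            "decision_tree": 3, "naive_bayes": 2, "svm": 6, "knn": 6, "neural_network": 5,
        }

    def test_names_unique_and_include_medium_gaussian(self):
        names = [c.preset_name for c in classifier_registry()]
        assert len(set(names)) == 22
        assert "Medium Gaussian SVM" in names
        assert "Linear SVM" in names


class TestConfusion:
    def test_all_correct(self):
        cm = confusion([1] * 4 + [0] * 4, [1] * 4 + [0] * 4)
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (4, 0, 0, 4)

    def test_all_positive_predictions(self):
        cm = confusion([1, 0, 0, 0], [1, 1, 1, 1])
        assert cm.tn == 0 and cm.fp == 3

    def test_hand_count(self):
        y_true = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
        y_pred = [1, 1, 1, 0, 1, 0, 0, 0, 0, 0]
        cm = confusion(y_true, y_pred)
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (3, 1, 1, 5)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion([1, 0], [1])


class TestMetrics:
    def test_perfect(self):
        m = metrics_from_confusion(ConfusionMatrix(4, 0, 0, 4))
        for k in ("accuracy", "sensitivity", "specificity", "precision", "f1", "gmean"):
            assert m[k] == pytest.approx(1.0)

    def test_hand_values(self):
        m = metrics_from_confusion(ConfusionMatrix(tp=3, fn=1, fp=1, tn=5))
        assert m["accuracy"] == pytest.approx(0.8)
        assert m["sensitivity"] == pytest.approx(0.75)
        assert m["specificity"] == pytest.approx(5 / 6)
        assert m["precision"] == pytest.approx(0.75)
        assert m["f1"] == pytest.approx(0.75)
        assert m["gmean"] == pytest.approx(np.sqrt(0.75 * 5 / 6))

    def test_degenerate_flags(self):
        m = metrics_from_confusion(ConfusionMatrix(tp=0, fn=0, fp=2, tn=3))
        assert m["sensitivity"] == 0.0
        assert "sensitivity" in m["degenerate"]

    def test_exhaustive_small_counts_match_formulas(self):
        for tp, fn, fp, tn in itertools.product(range(6), repeat=4):
            if tp + fn + fp + tn == 0:
                continue
            m = metrics_from_confusion(ConfusionMatrix(tp, fn, fp, tn))
            assert m["accuracy"] == pytest.approx((tp + tn) / (tp + fn + fp + tn))
            if tp + fn:
                assert m["sensitivity"] == pytest.approx(tp / (tp + fn))
            if fp + tn:
                assert m["specificity"] == pytest.approx(tn / (fp + tn))
            if tp + fp:
                assert m["precision"] == pytest.approx(tp / (tp + fp))
            assert m["gmean"] == pytest.approx(
                np.sqrt(m["sensitivity"] * m["specificity"])
            )


class TestAuc:
    def test_perfect_ordering(self):
        assert roc_auc([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1]) == pytest.approx(1.0)

    def test_all_ties_half(self):
        assert roc_auc([1, 0, 1, 0], [0.5] * 4) == pytest.approx(0.5)

    def test_hand_example(self):
        assert roc_auc([1, 0, 1, 0], [0.9, 0.8, 0.4, 0.2]) == pytest.approx(0.75)

    def test_single_class_raises(self):
        with pytest.raises(UndefinedAUCError):
            roc_auc([1, 1, 1], [0.1, 0.2, 0.3])

    def test_matches_pair_counting_on_random_batteries(self, rng):
        for _ in range(300):
            n = int(rng.integers(2, 13))
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            scores = np.round(rng.uniform(0, 1, n), 1)  # coarse grid forces ties
            assert roc_auc(y, scores) == pytest.approx(pair_count_auc(y, scores), abs=1e-12)


@pytest.fixture(scope="module")
def separable():
    r = np.random.default_rng(3)
    y = np.repeat([0, 1], 25)
    X = r.normal(size=(50, 4)) + 8.0 * y[:, None]
    return X, y


class TestCrossValidation:
    def test_separable_table_perfect_accuracy(self, separable):
        X, y = separable
        cfg = next(c for c in classifier_registry() if c.preset_name == "Linear SVM")
        m = stratified_kfold_eval(X, y, cfg, seed=0)
        assert m.accuracy == pytest.approx(1.0)
        assert m.auc == pytest.approx(1.0)
        assert m.n_folds == 5 and len(m.per_fold) == 5

    def test_deterministic_given_seed(self, separable):
        X, y = separable
        cfg = next(c for c in classifier_registry() if c.preset_name == "Medium KNN")
        a = stratified_kfold_eval(X, y, cfg, seed=5)
        b = stratified_kfold_eval(X, y, cfg, seed=5)
        assert a == b

    def test_permuted_labels_near_chance(self):
        r = np.random.default_rng(11)
        y = np.repeat([0, 1], 30)
        X = r.normal(size=(60, 10))
        cfg = next(c for c in classifier_registry() if c.preset_name == "Medium Gaussian SVM")
        m = stratified_kfold_eval(X, y, cfg, seed=1)
        band = 1.96 * np.sqrt(0.25 / 60)
        assert 0.5 - band <= m.accuracy <= 0.5 + band

    def test_class_too_small_raises(self):
        X = np.zeros((8, 2))
        y = np.array([0, 0, 0, 0, 0, 0, 1, 1])
        cfg = classifier_registry()[0]
        with pytest.raises(StratificationError):
            stratified_kfold_eval(X, y, cfg, n_folds=5)

    @pytest.mark.parametrize(
        "preset",
        ["Fine Tree", "Kernel Naive Bayes", "Weighted KNN", "Narrow Neural Network",
         "Cubic SVM", "Gaussian Naive Bayes"],
    )
    def test_every_family_runs_and_reports(self, separable, preset):
        X, y = separable
        cfg = next(c for c in classifier_registry() if c.preset_name == preset)
        m = stratified_kfold_eval(X, y, cfg, seed=2)
        assert 0.0 <= m.accuracy <= 1.0
        assert 0.0 <= m.auc <= 1.0
        assert m.accuracy >= 0.9  # strongly separated classes

    def test_coarse_knn_clamps_neighbors_to_training_size(self, separable):
        # 100 requested neighbors exceed the 40-sample training folds; the
        # clamp makes the vote near-global, so the preset runs but cannot
        # separate a tiny cohort well
        X, y = separable
        cfg = next(c for c in classifier_registry() if c.preset_name == "Coarse KNN")
        m = stratified_kfold_eval(X, y, cfg, seed=2)
        assert 0.0 <= m.accuracy <= 1.0
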