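import numpy as np
import pandas as pd
import pytest

from quspred.classify import (
    ClassifierConfig,
    auc_from_scores,
    bootstrap_auc,
    compute_metrics,
    knn_posterior,
    loocv_evaluate,
    posterior_separation_test,
    rank_features,
    sequential_forward_select,
)
from quspred.simulate import CohortSpec, generate_feature_cohort


def separated_cohort(effect=3.0, n_features=5, seed=0, n_good=42, n_poor=14):
    names = tuple(f"f{i+1}" for i in range(n_features))
    mean_good = np.zeros(n_features)
    mean_good[0] = effect
    spec = CohortSpec(names, mean_good, np.zeros(n_features), n_good=n_good, n_poor=n_poor, seed=seed)
    return generate_feature_cohort(spec)


class TestRanking:
    def test_shifted_feature_ranks_first(self):
        table, labels = separated_cohort(effect=3.0, seed=1)
        ranking = rank_features(table, labels, positive="good")
        assert ranking.features[0] == "f1"
        assert ranking.p_values[0] < 1e-3
        assert np.all(np.diff(ranking.p_values) >= 0)

    def test_skewed_feature_uses_mann_whitney(self):
        rng = np.random.default_rng(2)
        n = 60
        table = pd.DataFrame({"skewed": rng.lognormal(0, 2.0, n)})
        labels = pd.Series(["good"] * 40 + ["poor"] * 20)
        ranking = rank_features(table, labels, positive="good")
        assert ranking.tests[0] == "mann-whitney"

    def test_constant_feature_dropped(self):
        table, labels = separated_cohort(seed=3)
        table["flat"] = 1.0
        with pytest.warns(UserWarning, match="flat"):
            ranking = rank_features(table, labels, positive="good")
        assert "flat" not in ranking.features

    def test_single_class_rejected(self):
        table, labels = separated_cohort(seed=4)
        with pytest.raises(ValueError):
            rank_features(table, pd.Series("good", index=labels.index), positive="good")


class TestKNNPosterior:
    def test_worked_example(self):
        # neighbours at distances 1, 1, 2 with classes good, good, poor and
        # W = 1/d: P(good) = 2 / 2.5 = 0.8
        X = np.array([[1.0], [-1.0], [2.0]])
        y = np.array(["good", "good", "poor"], dtype=object)
        p = knn_posterior(np.array([0.0]), X, y, k=3, positive="good")
        assert p == pytest.approx(0.8, abs=1e-6)

    def test_unanimous_neighbourhood(self):
        X = np.array([[1.0], [2.0], [3.0]])
        y = np.array(["good"] * 3, dtype=object)
        assert knn_posterior(np.array([0.0]), X, y, 3, "good") == 1.0

    def test_posteriors_form_distribution(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 4))
        y = np.array(["good"] * 15 + ["poor"] * 15, dtype=object)
        for _ in range(100):
            x = rng.normal(size=4)
            p_good = knn_posterior(x, X, y, 5, "good")
            p_poor = knn_posterior(x, X, y, 5, "poor")
            assert 0.0 <= p_good <= 1.0
            assert p_good + p_poor == pytest.approx(1.0, abs=1e-12)

    def test_k_exceeding_training_size_rejected(self):
        X = np.zeros((3, 1))
        y = np.array(["good", "poor", "good"], dtype=object)
        with pytest.raises(ValueError):
            knn_posterior(np.zeros(1), X, y, 4, "good")


class TestMetrics:
    def test_study_scale_worked_example(self):
        # TP=38 FN=4 TN=11 FP=3 out of 42 good / 14 poor
        labels = np.array(["good"] * 42 + ["poor"] * 14, dtype=object)
        preds = np.array(["good"] * 38 + ["poor"] * 4 + ["poor"] * 11 + ["good"] * 3, dtype=object)
        m = compute_metrics(preds, labels, positive="good")
        assert m["sensitivity_pct"] == pytest.approx(90.5, abs=0.05)
        assert m["specificity_pct"] == pytest.approx(78.6, abs=0.05)
        assert m["accuracy_pct"] == pytest.approx(87.5, abs=1e-9)

    def test_perfect_and_degenerate_cases(self):
        labels = np.array(["good", "good", "poor"], dtype=object)
        m = compute_metrics(labels, labels, "good")
        assert (m["sensitivity_pct"], m["specificity_pct"], m["accuracy_pct"]) == (100, 100, 100)
        all_pos = np.array(["good"] * 3, dtype=object)
        assert compute_metrics(all_pos, labels, "good")["specificity_pct"] == 0.0


class TestAUC:
    def brute_force_auc(self, scores, labels, positive):
        pos = scores[labels == positive]
        neg = scores[labels != positive]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        return wins / (len(pos) * len(neg))

    def test_equals_pair_counting_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            n = 25
            scores = np.round(rng.normal(size=n), 1)  # induce ties
            labels = np.array(["good"] * 15 + ["poor"] * 10, dtype=object)
            got = auc_from_scores(scores, labels, "good")
            assert got == pytest.approx(self.brute_force_auc(scores, labels, "good"), abs=1e-12)

    def test_perfect_separation_ci(self):
        scores = np.array([1.0] * 10 + [0.0] * 5)
        labels = np.array(["good"] * 10 + ["poor"] * 5, dtype=object)
        auc, (lo, hi) = bootstrap_auc(scores, labels, "good", n_boot=1000, seed=0)
        assert auc == 1.0 and (lo, hi) == (1.0, 1.0)

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(7)
        scores = rng.normal(size=200)
        labels = np.array(["good"] * 100 + ["poor"] * 100, dtype=object)
        auc, (lo, hi) = bootstrap_auc(scores, labels, "good", n_boot=500, seed=1)
        assert 0.4 < auc < 0.6
        assert lo <= auc <= hi


class TestSFFS:
    def test_single_informative_feature_selected(self):
        table, labels = separated_cohort(effect=3.0, n_features=5, seed=8)
        selected = sequential_forward_select(table, labels, "knn", "good")
        assert selected[0] == "f1"
        # greedy add-only scan: later noise features enter only on a strict
        # LOOCV accuracy improvement, so the model stays small
        assert len(selected) <= 3

    def test_duplicated_feature_rejected(self):
        table, labels = separated_cohort(effect=3.0, n_features=2, seed=9)
        table["f1_copy"] = table["f1"]
        selected = sequential_forward_select(table, labels, "knn", "good")
        assert not {"f1", "f1_copy"}.issubset(set(selected))

    def test_single_feature_returned(self):
        table, labels = separated_cohort(effect=2.0, n_features=1, seed=10)
        assert sequential_forward_select(table, labels, "knn", "good") == ["f1"]


class TestLOOCV:
    def test_separated_cohort_reaches_bayes_level_accuracy(self):
        """A 3-sigma mean separation has a Bayes accuracy of ~94.5% at the
        42/14 class imbalance; the selected k-NN should land within binomial
        sampling error of that bound."""
        table, labels = separated_cohort(effect=3.0, seed=11)
        result = loocv_evaluate(
            table, labels, classifier="knn", positive="good", selection="global", seed=11
        )
        assert result.accuracy_pct >= 94.5 - 3 * 100 * np.sqrt(0.945 * 0.055 / 56)
        assert result.auc >= 0.9
        assert result.separation_p < 1e-3

    @pytest.mark.parametrize("classifier", ["fld", "svm"])
    def test_other_classifiers_separate_too(self, classifier):
        table, labels = separated_cohort(effect=3.0, n_features=2, seed=12)
        cfg = ClassifierConfig(tune=False)
        result = loocv_evaluate(table, labels, classifier=classifier, positive="good", cfg=cfg, seed=12)
        assert result.accuracy_pct >= 85.0
        assert result.auc >= 0.9

    def test_label_permutation_breaks_performance(self):
        """Leakage guard: permuted labels must give chance-level AUC and
        accuracy inside the binomial null band around the majority rate."""
        table, labels = separated_cohort(effect=3.0, seed=13)
        rng = np.random.default_rng(13)
        permuted = pd.Series(rng.permutation(labels.to_numpy()), index=labels.index)
        result = loocv_evaluate(table, permuted, classifier="knn", positive="good", seed=13)
        assert 0.4 <= result.auc <= 0.6
        majority = 75.0  # 42 of 56
        band = 3 * 100 * np.sqrt(0.75 * 0.25 / 56)
        assert result.accuracy_pct <= majority + band

    def test_deterministic(self):
        table, labels = separated_cohort(effect=1.0, seed=14)
        a = loocv_evaluate(table, labels, "knn", "good", seed=3)
        b = loocv_evaluate(table, labels, "knn", "good", seed=3)
        pd.testing.assert_series_equal(a.predictions, b.predictions)
        assert a.auc == b.auc and a.auc_ci == b.auc_ci

    def test_test_fold_label_cannot_leak(self):
        """Flipping one patient's label never changes that patient's own
        prediction (the training fold excludes it)."""
        table, labels = separated_cohort(effect=1.0, n_features=3, seed=15, n_good=12, n_poor=8)
        target = table.index[0]
        flipped = labels.copy()
        flipped[target] = "poor" if labels[target] == "good" else "good"
        a = loocv_evaluate(table, labels, "knn", "good", seed=0)
        b = loocv_evaluate(table, flipped, "knn", "good", seed=0)
        assert a.predictions[target] == b.predictions[target]
        assert a.posteriors[target] == b.posteriors[target]


class TestPosteriorSeparation:
    def test_perfectly_separated_posteriors(self):
        post = np.array([1.0] * 42 + [0.0] * 14)
        labels = np.array(["good"] * 42 + ["poor"] * 14, dtype=object)
        p = posterior_separation_test(post, labels, "good")
        # minimal attainable Mann-Whitney p for groups of 42 and 14
        assert p < 1e-8

    def test_identical_distributions_not_significant(self):
        rng = np.random.default_rng(16)
        ps = []
        for seed in range(50):
            post = rng.uniform(size=40)
            labels = np.array(["good"] * 25 + ["poor"] * 15, dtype=object)
            ps.append(posterior_separation_test(post, labels, "good"))
        assert np.mean(np.array(ps) < 0.05) < 0.2
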