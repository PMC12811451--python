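"""ROC construction, AUROC = Mann-Whitney concordance, Youden optimum,
operating points, and the two-method comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fluidtraj import (
    DegenerateInputError,
    ScoreParameters,
    ScoreResult,
    compare_methods,
    evaluate_scores,
    operating_point,
    optimal_threshold,
    roc_curve,
)


def mann_whitney_concordance(scores, labels):
    """Brute-force pairwise concordance: P(score_pos > score_neg) + 1/2 ties."""
    pos = [s for s, l in zip(scores, labels) if l == "changing"]
    neg = [s for s, l in zip(scores, labels) if l == "stable"]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def random_scored_labels(rng, n):
    labels = rng.choice(["stable", "changing"], size=n)
    if (labels == "changing").all():
        labels[0] = "stable"
    if (labels == "stable").all():
        labels[0] = "changing"
    # mixture with frequent ties to exercise the tie handling
    scores = rng.choice([0.0, 1.0, 2.5, 2.5, 4.0, rng.normal()], size=n)
    return scores, list(labels)


class TestRocCurve:
    def test_perfect_separation(self):
        roc = roc_curve([5, 6, 7, 1, 2, 3], ["changing"] * 3 + ["stable"] * 3)
        assert roc.auroc == 1.0

    def test_all_scores_equal_gives_chance(self):
        roc = roc_curve([2.0] * 6, ["changing"] * 3 + ["stable"] * 3)
        assert roc.auroc == 0.5

    def test_six_score_example_matches_pair_enumeration(self):
        scores = [3, 2, 1, 2, 0, -1]
        labels = ["changing", "changing", "stable", "stable", "stable", "stable"]
        roc = roc_curve(scores, labels)
        assert roc.auroc == pytest.approx(mann_whitney_concordance(scores, labels))

    def test_anchored_at_corners(self):
        roc = roc_curve([1, 2, 3, 4], ["stable", "changing", "stable", "changing"])
        assert (roc.fpr[0], roc.tpr[0]) == (0.0, 0.0)
        assert (roc.fpr[-1], roc.tpr[-1]) == (1.0, 1.0)
        assert np.all(np.diff(roc.tpr) >= 0) and np.all(np.diff(roc.fpr) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateInputError):
            roc_curve([1, 2], ["stable", "stable"])

    @given(n=st.integers(4, 50), seed=st.integers(0, 5000))
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_auroc_equals_mann_whitney_concordance(self, n, seed):
        rng = np.random.default_rng(seed)
        scores, labels = random_scored_labels(rng, n)
        roc = roc_curve(scores, labels)
        assert roc.auroc == pytest.approx(mann_whitney_concordance(scores, labels), abs=1e-12)

    @given(n=st.integers(4, 30), seed=st.integers(0, 3000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_monotone_transform_leaves_roc_unchanged(self, n, seed):
        rng = np.random.default_rng(seed)
        scores, labels = random_scored_labels(rng, n)
        base = roc_curve(scores, labels)
        trans = roc_curve(np.exp(0.5 * np.asarray(scores)), labels)
        assert trans.auroc == pytest.approx(base.auroc, abs=1e-12)
        np.testing.assert_allclose(trans.tpr, base.tpr)
        np.testing.assert_allclose(trans.fpr, base.fpr)

    @given(n=st.integers(4, 30), seed=st.integers(0, 3000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_label_flip_mirrors_auroc(self, n, seed):
        rng = np.random.default_rng(seed)
        scores, labels = random_scored_labels(rng, n)
        flipped = ["stable" if l == "changing" else "changing" for l in labels]
        assert roc_curve(scores, flipped).auroc == pytest.approx(
            1.0 - roc_curve(scores, labels).auroc, abs=1e-12
        )


class TestOptimalThreshold:
    def test_perfect_separation_is_perfect_point(self):
        res = evaluate_scores([5, 6, 7, 1, 2, 3], ["changing"] * 3 + ["stable"] * 3)
        assert res.optimal_sens == 1.0 and res.optimal_spec == 1.0 and res.optimal_acc == 1.0
        assert res.optimal_threshold == 3  # the highest stable score: J=1 exactly there

    def test_all_equal_ties_break_toward_sensitivity(self):
        res = evaluate_scores([2.0] * 6, ["changing"] * 3 + ["stable"] * 3)
        assert res.optimal_sens == 1.0 and res.optimal_spec == 0.0
        assert res.optimal_threshold < 2.0  # everything called changing

    def test_matches_exhaustive_youden_scan(self):
        rng = np.random.default_rng(31)
        scores, labels = random_scored_labels(rng, 20)
        res = evaluate_scores(scores, labels)
        best_j = -np.inf
        for thr in np.unique(scores):
            sens, spec, _ = operating_point(scores, labels, thr)
            best_j = max(best_j, sens + spec - 1)
        sens, spec, _ = operating_point(scores, labels, -np.inf)
        best_j = max(best_j, sens + spec - 1)
        assert res.optimal_sens - (1 - res.optimal_spec) == pytest.approx(best_j, abs=1e-12)

    def test_max_accuracy_criterion_available(self):
        scores = [4, 3, 2, 1, 0, -1, -2]
        labels = ["changing", "changing", "stable", "changing", "stable", "stable", "stable"]
        res = evaluate_scores(scores, labels, criterion="accuracy")
        accs = []
        for thr in list(np.unique(scores)) + [-np.inf]:
            accs.append(operating_point(scores, labels, thr)[2])
        assert res.optimal_acc == pytest.approx(max(accs))

    @given(n=st.integers(4, 30), seed=st.integers(0, 3000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_operating_point_reproduces_optimal_rates(self, n, seed):
        rng = np.random.default_rng(seed)
        scores, labels = random_scored_labels(rng, n)
        res = evaluate_scores(scores, labels)
        sens, spec, acc = operating_point(scores, labels, res.optimal_threshold)
        assert sens == pytest.approx(res.optimal_sens, abs=1e-12)
        assert spec == pytest.approx(res.optimal_spec, abs=1e-12)
        assert acc == pytest.approx(res.optimal_acc, abs=1e-12)

    def test_auroc_cross_checked_against_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(13)
        scores, labels = random_scored_labels(rng, 40)
        y = [1 if l == "changing" else 0 for l in labels]
        assert roc_curve(scores, labels).auroc == pytest.approx(
            roc_auc_score(y, scores), abs=1e-12
        )


class TestOperatingPoint:
    def test_threshold_below_all(self):
        sens, spec, _ = operating_point([1, 2, 3], ["changing", "stable", "changing"], 0.0)
        assert sens == 1.0 and spec == 0.0

    def test_threshold_above_all(self):
        sens, spec, _ = operating_point([1, 2, 3], ["changing", "stable", "changing"], 5.0)
        assert sens == 0.0 and spec == 1.0

    def test_ten_vu_contingency_arithmetic(self):
        # the confusion matrix TP=82 FN=25 TN=179 FP=10 on 107 changing /
        # 189 stable trajectories
        scores = [1.0] * 82 + [-1.0] * 25 + [-1.0] * 179 + [1.0] * 10
        labels = ["changing"] * 107 + ["stable"] * 189
        sens, spec, acc = operating_point(scores, labels, 0.0)
        assert sens == pytest.approx(82 / 107)
        assert spec == pytest.approx(179 / 189)
        assert acc == pytest.approx(261 / 296)
        assert round(100 * sens, 1) == 76.6
        assert round(100 * spec, 1) == 94.7

    def test_no_positives_yields_nan_with_warning(self):
        with pytest.warns(UserWarning):
            sens, spec, acc = operating_point([1, 2], ["stable", "stable"], 0.5)
        assert np.isnan(sens) and spec == 0.0


class TestCompareMethods:
    def _scores(self, snrs, amps):
        return [
            ScoreResult(
                signal_a=1, noise_sdt=1, snr=s, pop_amplitude=a, rcv=2.77,
                argmax_day=0, argmin_day=0,
            )
            for s, a in zip(snrs, amps)
        ]

    def test_snr_separates_but_amplitude_does_not(self):
        labels = ["changing"] * 3 + ["stable"] * 3
        scores = self._scores([9, 8, 7, 1, 2, 3], [5, 5, 5, 5, 5, 5])
        comp = compare_methods(scores, labels)
        assert comp.roc_personalized.auroc == 1.0
        assert comp.roc_personalized.auroc > comp.roc_population.auroc

    def test_identical_scores_identical_rocs(self):
        labels = ["changing"] * 3 + ["stable"] * 3
        vals = [9, 8, 1, 7, 2, 3]
        comp = compare_methods(self._scores(vals, vals), labels)
        np.testing.assert_allclose(comp.roc_personalized.tpr, comp.roc_population.tpr)
        np.testing.assert_allclose(comp.roc_personalized.fpr, comp.roc_population.fpr)
        assert comp.roc_personalized.auroc == comp.roc_population.auroc

    def test_fixed_cutoff_points_use_strict_rule(self):
        labels = ["changing", "stable"]
        comp = compare_methods(self._scores([2.8, 0.1], [10.0, 3.0]), labels)
        sens, spec, _ = comp.snr_cutoff_point
        assert sens == 0.0  # exactly 2.8 is not above the cutoff
        sens_vu, spec_vu, _ = comp.vu_cutoff_point
        assert sens_vu == 0.0  # exactly 10 VU is stable
        assert spec == 1.0 and spec_vu == 1.0
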