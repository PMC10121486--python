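import itertools
import math

import numpy as np
import pytest

from asbestoscreen.classifier import ClassifierConfig, ResNet3dClassifier
from asbestoscreen.evaluation import (
    agreement_stratified_report,
    mcnemar_test,
    roc_auc,
    saliency_map,
    threshold_metrics,
)


def auc_by_pair_counting(scores, labels):
    """Independent oracle: enumerate every label-discordant pair."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def mcnemar_exact_by_enumeration(b, c):
    """Two-sided exact McNemar: fold the binomial(b + c, 1/2) tails."""
    n = b + c
    pmf = [math.comb(n, k) * 0.5**n for k in range(n + 1)]
    tail = sum(p for k, p in enumerate(pmf) if k <= min(b, c))
    return min(1.0, 2 * tail) if b != c else min(1.0, 2 * sum(pmf[: b + 1]) - pmf[b])


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1], n_boot=10)["auc"] == 1.0

    def test_all_tied_scores_give_half(self):
        assert roc_auc([0.5] * 6, [0, 1, 0, 1, 0, 1], n_boot=10)["auc"] == 0.5

    def test_four_case_worked_example(self):
        # pairs (0.35 vs 0.1, 0.4), (0.8 vs 0.1, 0.4): 3 wins of 4 -> 0.75
        assert roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1], n_boot=10)["auc"] == 0.75

    def test_matches_pair_counting_oracle(self, rng):
        scores = np.round(rng.uniform(size=50), 2)  # rounding forces ties
        labels = rng.integers(0, 2, size=50)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        res = roc_auc(scores, labels, n_boot=10)
        assert res["auc"] == pytest.approx(auc_by_pair_counting(scores, labels), abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.uniform(size=40)
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        a = roc_auc(scores, labels, n_boot=10)["auc"]
        assert roc_auc(np.exp(3 * scores), labels, n_boot=10)["auc"] == pytest.approx(a)
        assert roc_auc(scores**3, labels, n_boot=10)["auc"] == pytest.approx(a)

    def test_bootstrap_ci_brackets_point_and_is_seeded(self, rng):
        scores = rng.uniform(size=60)
        labels = (scores + rng.normal(0, 0.3, 60) > 0.5).astype(int)
        r1 = roc_auc(scores, labels, n_boot=200, seed=3)
        r2 = roc_auc(scores, labels, n_boot=200, seed=3)
        assert r1["ci"] == r2["ci"]
        assert r1["ci"][0] <= r1["auc"] <= r1["ci"][1]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])


class TestThresholdMetrics:
    def test_all_correct(self):
        m = threshold_metrics([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0], n_boot=10)
        for key in ("accuracy", "sensitivity", "specificity", "ppv", "npv"):
            assert m[key] == 1.0

    def test_hand_filled_confusion_table(self):
        m = threshold_metrics([0.9, 0.2, 0.8, 0.1], [1, 1, 0, 0], n_boot=10)
        assert m["sensitivity"] == 0.5
        assert m["specificity"] == 0.5
        assert m["accuracy"] == 0.5

    def test_no_predicted_positives_gives_nan_ppv(self):
        m = threshold_metrics([0.1, 0.2, 0.3], [0, 0, 1], n_boot=10)
        assert math.isnan(m["ppv"])
        assert m["npv"] == pytest.approx(2 / 3)


class TestMcNemar:
    def test_no_discordant_pairs(self):
        assert mcnemar_test([True, True, False], [True, True, False]) == 1.0

    def test_symmetric_discordance(self):
        a = [True] * 5 + [False] * 5 + [True] * 10
        b = [False] * 5 + [True] * 5 + [True] * 10
        assert mcnemar_test(a, b) == pytest.approx(1.0)

    def test_worked_example_b2_c10(self):
        a = [True] * 2 + [False] * 10 + [True] * 20
        b = [False] * 2 + [True] * 10 + [True] * 20
        assert mcnemar_test(a, b) == pytest.approx(0.038574, abs=1e-5)

    @pytest.mark.parametrize("b, c", [(b, c) for b in range(0, 7) for c in range(0, 13 - 6) if 0 < b + c <= 12])
    def test_exact_form_matches_binomial_tail_enumeration(self, b, c):
        correct_a = [True] * b + [False] * c + [True] * 5
        correct_b = [False] * b + [True] * c + [True] * 5
        assert mcnemar_test(correct_a, correct_b) == pytest.approx(
            mcnemar_exact_by_enumeration(b, c), abs=1e-9
        )

    def test_large_discordance_uses_continuity_corrected_chisquare(self):
        from scipy.stats import chi2

        b, c = 10, 30
        a_vec = [True] * b + [False] * c
        b_vec = [False] * b + [True] * c
        expected = float(chi2.sf((abs(b - c) - 1) ** 2 / (b + c), df=1))
        assert mcnemar_test(a_vec, b_vec) == pytest.approx(expected, abs=1e-9)


class TestStratifiedReport:
    def test_constant_scores(self):
        rep = agreement_stratified_report([0.5] * 8, [0, 1, 2, 3] * 2)
        assert (rep["mean"] == 0.5).all()

    def test_empty_stratum_is_nan_not_crash(self):
        rep = agreement_stratified_report([0.2, 0.9], [0, 3])
        assert rep.loc[1, "n"] == 0 and math.isnan(rep.loc[1, "mean"])
        assert rep.loc[0, "mean"] == pytest.approx(0.2)

    def test_desk_run_predictions_rise_with_panel_agreement(self, desk):
        k = np.array([desk["cases"][i].votes.n_positive for i in desk["splits"]["test"]])
        rep = agreement_stratified_report(desk["predictions"]["soft"], k)
        assert rep.loc[3, "mean"] > rep.loc[0, "mean"]


class TestSaliency:
    def _tiny_model(self):
        cfg = ClassifierConfig(input_channels=1, stage_channels=(4, 8), blocks_per_stage=(0, 1), seed=0)
        return cfg, ResNet3dClassifier(cfg)

    def test_constant_model_gives_zero_map(self, rng):
        _, model = self._tiny_model()
        for p in model.head.parameters():
            p.value[...] = 0.0
        vol = rng.uniform(size=(16, 16, 8))
        sal = saliency_map(model, vol)
        assert sal.shape == vol.shape
        assert np.all(sal == 0.0)

    def test_map_is_aligned_nonnegative_and_normalised(self, rng):
        _, model = self._tiny_model()
        vol = rng.uniform(size=(16, 16, 8))
        sal = saliency_map(model, vol)
        assert sal.shape == vol.shape
        assert sal.min() >= 0.0
        assert sal.max() == pytest.approx(1.0)

    def test_gradient_free_model_rejected(self):
        with pytest.raises(TypeError):
            saliency_map(object(), np.zeros((8, 8, 8)))

    def test_desk_run_saliency_concentrates_on_lesions(self, desk):
        assert desk["saliency_fraction"] >= 0.7
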