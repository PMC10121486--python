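import math

import numpy as np
import pytest
from scipy.stats import spearmanr

from asbestoscreen.classifier import (
    ClassifierConfig,
    Label,
    ResNet3dClassifier,
    binary_cross_entropy,
    contradictory_mask,
    load_classifier,
    make_label,
    make_soft_label,
    predict,
    save_classifier,
    split_cohort,
    train_classifier,
)

TINY = ClassifierConfig(
    input_channels=1, stage_channels=(4, 8), blocks_per_stage=(0, 1),
    epochs=2, max_epochs=2, max_restarts=0, batch_size=4, seed=5,
)


class TestLabels:
    @pytest.mark.parametrize("votes, soft", [((1, 0, 0), 1 / 3), ((0, 0, 0), 0.0), ((1, 1, 1), 1.0)])
    def test_soft_label_is_the_positive_fraction(self, votes, soft):
        assert make_soft_label(votes) == pytest.approx(soft)

    def test_make_label_kinds(self):
        assert make_label((1, 1, 0), "hard") == Label("hard", 1.0)
        assert make_label((1, 0, 0), "hard") == Label("hard", 0.0)
        assert make_label((1, 0, 0), "soft").value == pytest.approx(1 / 3)

    def test_label_validation(self):
        with pytest.raises(ValueError):
            Label("hard", 0.5)
        with pytest.raises(ValueError):
            Label("soft", 1.5)
        with pytest.raises(ValueError):
            make_soft_label((1, 0))


class TestBinaryCrossEntropy:
    @pytest.mark.parametrize("y", [0.0, 1 / 3, 1.0])
    def test_half_prediction_is_ln2_for_any_target(self, y):
        assert binary_cross_entropy(0.5, y) == pytest.approx(math.log(2))

    def test_confident_correct_prediction_is_near_zero(self):
        assert binary_cross_entropy(1.0, Label("hard", 1.0)) < 1e-6

    def test_soft_target_worked_example(self):
        # -[(1/3) ln 0.9 + (2/3) ln 0.1] = 1.5701...
        assert binary_cross_entropy(0.9, 1 / 3) == pytest.approx(1.5701, abs=1e-4)

    def test_extreme_predictions_are_clamped_not_infinite(self):
        assert math.isfinite(binary_cross_entropy(0.0, 1.0))
        assert binary_cross_entropy(0.0, 1.0) == pytest.approx(-math.log(1e-7))


class TestSplitCohort:
    def _cohort(self, n_pos, n_neg):
        return [(i, i < n_pos) for i in range(n_pos + n_neg)]

    def test_stratification_preserves_the_class_ratio(self):
        splits = split_cohort(self._cohort(50, 50), fractions=(0.6, 0.2, 0.2), seed=1)
        for part, size in zip(splits, (60, 20, 20)):
            assert len(part) == size
            assert sum(1 for _, v in part if v) == size // 2

    def test_partition_union_and_disjointness(self):
        cohort = self._cohort(37, 63)
        splits = split_cohort(cohort, seed=9)
        ids = [i for part in splits for i, _ in part]
        assert sorted(ids) == list(range(100))

    def test_reproducible_under_seed(self):
        cohort = self._cohort(20, 30)
        assert split_cohort(cohort, seed=4) == split_cohort(cohort, seed=4)
        assert split_cohort(cohort, seed=4) != split_cohort(cohort, seed=5)

    def test_empty_stratum_rejected(self):
        with pytest.raises(ValueError):
            split_cohort(self._cohort(10, 0), seed=0)


class TestModelContracts:
    def test_probability_in_open_interval(self, rng):
        model = ResNet3dClassifier(TINY)
        p = predict(model, rng.uniform(size=(16, 16, 8)))
        assert 0.0 < p < 1.0

    def test_single_channel_model_ignores_heatmap(self, rng):
        model = ResNet3dClassifier(TINY)
        vol = rng.uniform(size=(16, 16, 8))
        assert predict(model, vol) == predict(model, vol, heatmap=rng.uniform(size=(16, 16, 8)))

    def test_two_channel_model_requires_heatmap(self, rng):
        cfg = ClassifierConfig(input_channels=2, stage_channels=(4, 8), blocks_per_stage=(0, 1), seed=5)
        model = ResNet3dClassifier(cfg)
        with pytest.raises(ValueError):
            predict(model, rng.uniform(size=(16, 16, 8)))

    def test_dlco_model_requires_dlco(self, rng):
        cfg = ClassifierConfig(
            input_channels=1, use_dlco_input=True, stage_channels=(4, 8), blocks_per_stage=(0, 1), seed=5
        )
        model = ResNet3dClassifier(cfg)
        vol = rng.uniform(size=(16, 16, 8))
        with pytest.raises(ValueError):
            predict(model, vol)
        assert 0.0 < predict(model, vol, dlco_pct=62.0) < 1.0

    def test_checkpoint_roundtrip(self, rng, tmp_path):
        model = ResNet3dClassifier(TINY)
        vol = rng.uniform(size=(16, 16, 8))
        save_classifier(model, tmp_path / "clf.npz")
        clone = load_classifier(tmp_path / "clf.npz")
        assert predict(clone, vol) == pytest.approx(predict(model, vol))


class TestTraining:
    def _toy_data(self, rng, n=16):
        x = rng.uniform(0, 0.2, size=(n, 1, 16, 16, 8)).astype(np.float32)
        y = rng.integers(0, 2, size=n).astype(float)
        x[y == 1, :, 4:12, 4:12, 2:6] += 0.5
        return x, y

    def test_channel_mismatch_rejected(self, rng):
        x, y = self._toy_data(rng)
        bad = ClassifierConfig(input_channels=2, stage_channels=(4,), blocks_per_stage=(1,))
        with pytest.raises(ValueError):
            train_classifier(x, y, x, y, bad)

    def test_dlco_config_requires_dlco_arrays(self, rng):
        x, y = self._toy_data(rng)
        cfg = ClassifierConfig(
            input_channels=1, use_dlco_input=True, stage_channels=(4,), blocks_per_stage=(1,), epochs=1
        )
        with pytest.raises(ValueError):
            train_classifier(x, y, x, y, cfg)

    def test_seeded_determinism(self, rng):
        x, y = self._toy_data(rng)
        a = train_classifier(x[:12], y[:12], x[12:], y[12:], TINY)
        b = train_classifier(x[:12], y[:12], x[12:], y[12:], TINY)
        assert a.history == b.history

    def test_learns_an_obvious_contrast(self, rng):
        x, y = self._toy_data(rng, n=32)
        cfg = ClassifierConfig(
            input_channels=1, stage_channels=(4, 8), blocks_per_stage=(0, 1),
            epochs=12, max_epochs=24, max_restarts=1, batch_size=8, seed=2,
        )
        model = train_classifier(x[:24], y[:24], x[24:], y[24:], cfg)
        preds = model.predict_proba(x[24:])
        assert np.mean((preds >= 0.5) == (y[24:] == 1)) >= 0.75


class TestDeskRunProperties:
    def test_heldout_auc_against_majority_verdict(self, desk):
        assert desk["auc_imaging"]["auc"] >= 0.85

    def test_predictions_separate_the_verdict_groups(self, desk):
        preds, labels = desk["predictions"]["soft"], desk["labels_test"]
        assert preds[labels == 1].mean() > preds[labels == 0].mean()

    def test_predicted_probability_tracks_imaging_severity(self, desk):
        sev = np.array([desk["cases"][i].severity_img for i in desk["splits"]["test"]])
        rho = spearmanr(desk["predictions"]["soft"], sev).statistic
        assert rho >= 0.7

    def test_training_never_reads_test_cases(self, desk):
        s = desk["splits"]
        assert not (set(s["train"]) & set(s["test"]))
        assert not (set(s["val"]) & set(s["test"]))

    def test_contradictory_cases_are_routed_out_of_the_splits(self, desk):
        flagged = set(np.flatnonzero(desk["contradictory"]))
        in_splits = set(desk["splits"]["train"]) | set(desk["splits"]["val"]) | set(desk["splits"]["test"])
        assert not (flagged & in_splits)


def test_contradictory_mask_flags_kind_verdict_mismatches():
    class Case:
        def __init__(self, kind, sev, verdict):
            self.lesion_kind = kind
            self.severity_img = sev
            self.verdict = verdict

    cases = [
        Case("nonasbestos_ild", 0.8, False),  # ILD pattern, no asbestosis verdict
        Case("plaques_only", 0.5, True),      # positive verdict without parenchymal disease
        Case("asbestosis_fibrosis", 0.7, True),
        Case("none", 0.0, False),
    ]
    assert contradictory_mask(cases).tolist() == [True, True, False, False]
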