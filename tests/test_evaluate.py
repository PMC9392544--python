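"""Fold planning, metric formulas (against sklearn and brute force), and the
cross-validation driver."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from eegresp import (
    ArchitectureSpec,
    AugmentConfig,
    ConfusionMatrix,
    CrossValidation,
    LayerSpec,
    SegmentTensor,
    TrainConfig,
    cohen_kappa,
    make_fold_plan,
    roc_auc,
    sensitivity_specificity_accuracy,
)
from eegresp.evaluate import (
    FoldPlan,
    UndefinedMetricError,
    confusion_from_predictions,
)
from eegresp.recording import make_meta


def labelled_tensor(n_per_class=50, n_subjects_per_class=5, seg_len=16, n_ch=2,
                    seed=0, effect=0.0):
    """Toy tensor: ``n_per_class`` epochs per class spread over subjects."""
    rng = np.random.default_rng(seed)
    parts = []
    per_subj = n_per_class // n_subjects_per_class
    for cls in (0, 1):
        for s in range(n_subjects_per_class):
            data = rng.standard_normal((per_subj, seg_len, n_ch))
            if cls == 1:
                data += effect * np.sin(
                    2 * np.pi * 4 * np.arange(seg_len) / seg_len)[None, :, None]
            meta = make_meta(per_subj, f"c{cls}s{s}", "pre", "eyes_closed",
                             cls, np.arange(per_subj) * seg_len)
            parts.append(SegmentTensor(data, meta))
    return SegmentTensor.concatenate(parts)


class TestFoldPlan:
    def test_segment_level_exact_stratification(self):
        t = labelled_tensor(50, 5)
        plan = make_fold_plan(t, n_folds=10, policy="segment_level", seed=0)
        labels = t.labels
        for f in range(10):
            _, _, test_idx = plan.indices(f)
            assert (labels[test_idx] == 0).sum() == 5
            assert (labels[test_idx] == 1).sum() == 5

    def test_global_split_is_70_20_10(self):
        t = labelled_tensor(500, 5)
        plan = make_fold_plan(t, n_folds=10, policy="segment_level", seed=1)
        train_idx, val_idx, test_idx = plan.indices(0)
        n = t.n_segments
        assert test_idx.size == pytest.approx(0.1 * n, rel=0.02)
        assert val_idx.size == pytest.approx(0.2 * n, rel=0.05)
        assert train_idx.size == pytest.approx(0.7 * n, rel=0.02)

    def test_subject_level_folds_do_not_split_subjects(self):
        t = labelled_tensor(60, 6)
        plan = make_fold_plan(t, n_folds=3, policy="subject_level", seed=2)
        subjects = t.subject_ids
        for f in range(3):
            train_idx, val_idx, test_idx = plan.indices(f)
            for part_a, part_b in [(train_idx, test_idx), (val_idx, test_idx),
                                   (train_idx, val_idx)]:
                assert not (set(subjects[part_a]) & set(subjects[part_b]))

    def test_every_segment_tested_exactly_once(self):
        t = labelled_tensor(40, 4)
        plan = make_fold_plan(t, n_folds=4, policy="segment_level", seed=3)
        counts = np.zeros(t.n_segments, dtype=int)
        for f in range(4):
            _, _, test_idx = plan.indices(f)
            counts[test_idx] += 1
        assert np.all(counts == 1)

    def test_insufficient_segments_error(self):
        t = labelled_tensor(5, 1)
        with pytest.raises(ValueError, match="class"):
            make_fold_plan(t, n_folds=10, policy="segment_level", seed=0)

    def test_csv_round_trip(self, tmp_path):
        t = labelled_tensor(30, 3)
        plan = make_fold_plan(t, n_folds=3, policy="segment_level", seed=4)
        path = tmp_path / "plan.csv"
        plan.to_csv(path)
        back = FoldPlan.from_csv(path)
        assert back.n_folds == 3
        assert np.array_equal(back.assignments, plan.assignments)
        for f in range(3):
            for a, b in zip(back.indices(f), plan.indices(f)):
                assert np.array_equal(a, b)

    def test_determinism(self):
        t = labelled_tensor(30, 3)
        a = make_fold_plan(t, 3, "segment_level", seed=5)
        b = make_fold_plan(t, 3, "segment_level", seed=5)
        assert np.array_equal(a.assignments, b.assignments)


class TestRateMetrics:
    def test_hand_arithmetic(self):
        cm = ConfusionMatrix(tp=90, fn=10, tn=80, fp=20)
        m = sensitivity_specificity_accuracy(cm)
        assert m["sensitivity"] == pytest.approx(0.9)
        assert m["specificity"] == pytest.approx(0.8)
        assert m["overall_accuracy"] == pytest.approx(0.85)
        assert m["precision"] == pytest.approx(90 / 110)
        f1 = 2 * m["precision"] * m["sensitivity"] / (m["precision"] + m["sensitivity"])
        assert m["f_measure"] == pytest.approx(f1)

    def test_perfect_and_inverted(self):
        perfect = sensitivity_specificity_accuracy(ConfusionMatrix(tp=5, tn=5))
        assert all(v == 1.0 for v in perfect.values())
        inverted = sensitivity_specificity_accuracy(
            ConfusionMatrix(tp=0, fn=5, tn=0, fp=5))
        assert inverted["sensitivity"] == 0.0
        assert inverted["specificity"] == 0.0

    def test_zero_denominator_flagged(self):
        with pytest.raises(UndefinedMetricError):
            sensitivity_specificity_accuracy(ConfusionMatrix(tn=5, fp=5))

    def test_matches_sklearn(self):
        from sklearn.metrics import accuracy_score, f1_score, precision_score, recall_score
        rng = np.random.default_rng(0)
        y_true = rng.integers(0, 2, 200)
        y_pred = rng.integers(0, 2, 200)
        cm = confusion_from_predictions(y_true, y_pred)
        m = sensitivity_specificity_accuracy(cm)
        assert m["overall_accuracy"] == pytest.approx(accuracy_score(y_true, y_pred))
        assert m["sensitivity"] == pytest.approx(recall_score(y_true, y_pred))
        assert m["precision"] == pytest.approx(precision_score(y_true, y_pred))
        assert m["f_measure"] == pytest.approx(f1_score(y_true, y_pred))

    @given(tp=st.integers(0, 50), fp=st.integers(0, 50),
           tn=st.integers(0, 50), fn=st.integers(0, 50))
    @settings(max_examples=100, deadline=None)
    def test_accuracy_error_identity(self, tp, fp, tn, fn):
        cm = ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)
        if cm.total == 0 or tp + fn == 0 or tn + fp == 0 or tp + fp == 0:
            return
        m = sensitivity_specificity_accuracy(cm)
        assert m["overall_accuracy"] == pytest.approx(1 - (fp + fn) / cm.total)


class TestKappa:
    def test_perfect_agreement(self):
        assert cohen_kappa(ConfusionMatrix(tp=7, tn=3)) == pytest.approx(1.0)

    def test_chance_level_agreement(self):
        # marginals independent: p_o = p_e exactly
        assert cohen_kappa(ConfusionMatrix(tp=30, fn=30, fp=20, tn=20)) == pytest.approx(0.0)

    def test_direct_formula_value(self):
        # p_o = .85, p_e = .5 -> kappa = .7
        assert cohen_kappa(ConfusionMatrix(tp=90, fn=10, tn=80, fp=20)) == pytest.approx(0.7)

    def test_matches_sklearn(self):
        from sklearn.metrics import cohen_kappa_score
        rng = np.random.default_rng(1)
        for _ in range(20):
            y_true = rng.integers(0, 2, 100)
            y_pred = rng.integers(0, 2, 100)
            cm = confusion_from_predictions(y_true, y_pred)
            assert cohen_kappa(cm) == pytest.approx(
                cohen_kappa_score(y_true, y_pred), abs=1e-12)

    def test_degenerate_marginals_warn_zero(self):
        with pytest.warns(RuntimeWarning):
            assert cohen_kappa(ConfusionMatrix(tp=10)) == 0.0


class TestAUC:
    def test_perfectly_separated(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        labels = np.array([0, 0, 1, 1])
        assert roc_auc(scores, labels) == 1.0

    def test_all_ties(self):
        assert roc_auc(np.full(10, 0.5), np.arange(10) % 2) == 0.5

    def test_matches_pairwise_bruteforce_and_sklearn(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(2)
        for _ in range(10):
            labels = rng.integers(0, 2, 20)
            if labels.min() == labels.max():
                continue
            scores = np.round(rng.uniform(0, 1, 20), 1)  # induce ties
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            brute = np.mean([(1.0 if p > q else 0.5 if p == q else 0.0)
                             for p in pos for q in neg])
            assert roc_auc(scores, labels) == pytest.approx(brute)
            assert roc_auc(scores, labels) == pytest.approx(roc_auc_score(labels, scores))

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        scores = rng.uniform(0, 1, 50)
        labels = rng.integers(0, 2, 50)
        base = roc_auc(scores, labels)
        for f in (lambda s: 3 * s + 1, np.exp, lambda s: s ** 3):
            assert roc_auc(f(scores), labels) == pytest.approx(base)

    def test_single_class_error(self):
        with pytest.raises(UndefinedMetricError):
            roc_auc(np.array([0.1, 0.9]), np.array([1, 1]))


def small_arch(seg_len=16, n_ch=2):
    return ArchitectureSpec(input_shape=(seg_len, n_ch), layers=(
        LayerSpec("conv1d", r=4, s=3),
        LayerSpec("maxpool1d", d=2),
        LayerSpec("lstm", r=4, return_sequence=False),
        LayerSpec("dense", r=2),
    ))


class TestCrossValidation:
    def test_confusion_total_equals_sum_of_test_sizes(self):
        t = labelled_tensor(40, 4, effect=1.5)
        cv = CrossValidation(t, arch=small_arch(),
                             train_cfg=TrainConfig(epochs=3, batch_size=16, seed=0),
                             n_folds=4, policy="segment_level", seed=0)
        report = cv.run()
        sizes = sum(cv.plan.indices(f)[2].size for f in range(4))
        assert report.confusion.total == sizes == t.n_segments
        assert len(report.per_fold) == 4

    def test_strong_effect_is_learnable(self):
        t = labelled_tensor(60, 6, effect=3.0, seed=4)
        cv = CrossValidation(t, arch=small_arch(),
                             train_cfg=TrainConfig(epochs=15, batch_size=16,
                                                   seed=0, patience=15),
                             n_folds=3, policy="segment_level", seed=1)
        report = cv.run()
        assert report.mean["overall_accuracy"] >= 0.85

    def test_augmented_segments_never_reach_validation_or_test(self):
        t = labelled_tensor(40, 4)
        plan = make_fold_plan(t, 4, "segment_level", seed=2)
        cv = CrossValidation(t, arch=small_arch(),
                             train_cfg=TrainConfig(epochs=2, batch_size=16, seed=0),
                             augment_cfg=AugmentConfig(n_folds=4, seed=0),
                             plan=plan)
        report = cv.run()
        # evaluated epochs are exactly the real segments of the fold plan
        assert report.confusion.total == t.n_segments
        assert not t.meta["is_artificial"].any()

    def test_report_serialisation(self, tmp_path):
        t = labelled_tensor(40, 4, effect=1.0)
        cv = CrossValidation(t, arch=small_arch(),
                             train_cfg=TrainConfig(epochs=2, batch_size=16, seed=0),
                             n_folds=4, policy="segment_level", seed=0)
        report = cv.run()
        report.to_csv(tmp_path / "m.csv")
        report.to_json(tmp_path / "m.json")
        frame = pd.read_csv(tmp_path / "m.csv")
        assert len(frame) == 4 + 2  # folds + mean + sd rows
        assert "mean" in frame["fold"].astype(str).tolist()
        summary = report.summary()
        assert "overall_accuracy" in summary and "folds" in summary
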