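"""Splits, ROC/AUC, threshold selection, confusion metrics, ablation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from conftest import make_dataset
from fogdetect.dataio import ValidationError
from fogdetect.evaluate import (
    FoldAssignment,
    confusion_metrics,
    cross_validate,
    gmean_threshold,
    grouped_kfold,
    holdout_split,
    mean_roc,
    roc_auc,
    run_sensor_ablation,
    select_configuration,
    subject_fog_percent,
)
from fogdetect.models import train_spectral_baseline


def mann_whitney_auc(y, p):
    """Independent oracle: AUC as the normalized Mann-Whitney U statistic."""
    pos = np.asarray(p)[np.asarray(y) == 1]
    neg = np.asarray(p)[np.asarray(y) == 0]
    u = stats.mannwhitneyu(pos, neg, alternative="two-sided").statistic
    return u / (len(pos) * len(neg))


class TestROC:
    def test_hand_enumerated_example(self):
        """Scores (0.1, 0.4, 0.35, 0.8), labels (0, 0, 1, 1): of the 4
        pos-neg pairs, 3 are won and 1 lost -> AUC 0.75."""
        _, _, auc = roc_auc(np.array([0, 0, 1, 1]), np.array([0.1, 0.4, 0.35, 0.8]))
        assert auc == pytest.approx(0.75)

    def test_perfect_separation(self):
        _, _, auc = roc_auc(np.array([0, 0, 1, 1]), np.array([0.1, 0.2, 0.8, 0.9]))
        assert auc == 1.0

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 10_000)
        p = rng.random(10_000)
        _, _, auc = roc_auc(y, p)
        assert 0.48 <= auc <= 0.52

    def test_matches_mann_whitney_on_random_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n = int(rng.integers(6, 40))
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            p = np.round(rng.random(n), 2)  # force ties
            _, _, auc = roc_auc(y, p)
            assert auc == pytest.approx(mann_whitney_auc(y, p), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc(np.ones(5), np.random.rand(5))


class TestMeanROC:
    def test_identical_folds_have_zero_sd(self):
        fpr = np.array([0.0, 0.5, 1.0])
        tpr = np.array([0.0, 0.8, 1.0])
        res = mean_roc([fpr, fpr], [tpr, tpr], [0.9, 0.9])
        assert np.all(res.sd_tpr == 0.0)
        assert res.sd_auc == 0.0

    def test_mean_and_population_sd_of_aucs(self):
        fpr = np.array([0.0, 1.0])
        tpr = np.array([0.0, 1.0])
        res = mean_roc([fpr, fpr], [tpr, tpr], [0.8, 0.9])
        assert res.mean_auc == pytest.approx(0.85)
        assert res.sd_auc == pytest.approx(0.05)

    def test_mean_curve_within_fold_envelope(self):
        rng = np.random.default_rng(2)
        fprs, tprs, aucs = [], [], []
        for _ in range(4):
            y = rng.integers(0, 2, 200)
            p = np.clip(y * 0.3 + rng.random(200) * 0.7, 0, 1)
            f, t, a = roc_auc(y, p)
            fprs.append(f)
            tprs.append(t)
            aucs.append(a)
        res = mean_roc(fprs, tprs, aucs)
        lo = np.min([np.interp(res.grid_fpr, f, t) for f, t in zip(fprs, tprs)], axis=0)
        hi = np.max([np.interp(res.grid_fpr, f, t) for f, t in zip(fprs, tprs)], axis=0)
        inner = slice(1, -1)
        assert np.all(res.mean_tpr[inner] >= lo[inner] - 1e-12)
        assert np.all(res.mean_tpr[inner] <= hi[inner] + 1e-12)


class TestGmeanThreshold:
    def test_perfect_classifier_reaches_gmean_one(self):
        y = np.array([0] * 5 + [1] * 5)
        p = np.array([0.1] * 5 + [0.9] * 5)
        choice = gmean_threshold(y, p)
        assert choice.gmean == pytest.approx(1.0)
        assert 0.1 < choice.threshold <= 0.9

    @settings(derandomize=True, max_examples=40)
    @given(st.integers(0, 10_000))
    def test_equals_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        n = 50
        y = rng.integers(0, 2, n)
        if y.min() == y.max():
            return
        p = np.round(rng.random(n), 2)
        choice = gmean_threshold(y, p)
        # brute force over every distinct score used as tau (p >= tau rule)
        best = -1.0
        for tau in np.unique(p):
            pred = p >= tau
            tpr = (pred & (y == 1)).sum() / (y == 1).sum()
            fpr = (pred & (y == 0)).sum() / (y == 0).sum()
            best = max(best, np.sqrt(tpr * (1 - fpr)))
        assert choice.gmean == pytest.approx(best, abs=1e-12)
        # returned operating point is self-consistent
        m = confusion_metrics(y, p, choice.threshold)
        assert np.sqrt(m.sensitivity * m.specificity) == pytest.approx(
            choice.gmean, abs=1e-12
        )


class TestConfusionMetrics:
    def test_known_confusion_table(self):
        y = np.array([1] * 100 + [0] * 100)
        p = np.array([0.9] * 85 + [0.1] * 15 + [0.9] * 32 + [0.1] * 68)
        m = confusion_metrics(y, p, 0.5)
        assert (m.tp, m.fn, m.fp, m.tn) == (85, 15, 32, 68)
        assert m.sensitivity == pytest.approx(0.85)
        assert m.specificity == pytest.approx(0.68)
        assert m.precision == pytest.approx(85 / 117, abs=1e-3)
        assert m.f_score == pytest.approx(2 * (85 / 117) * 0.85 / ((85 / 117) + 0.85))

    def test_all_correct_gives_ones(self):
        y = np.array([0, 0, 1, 1])
        m = confusion_metrics(y, np.array([0.1, 0.2, 0.9, 0.8]), 0.5)
        assert (m.sensitivity, m.specificity, m.precision, m.f_score) == (1, 1, 1, 1)

    def test_zero_threshold_predicts_everything_positive(self):
        y = np.array([0, 1, 0, 1])
        m = confusion_metrics(y, np.array([0.2, 0.3, 0.4, 0.5]), 0.0)
        assert m.sensitivity == 1.0
        assert m.specificity == 0.0

    def test_no_predicted_positives_yields_nan_precision(self):
        y = np.array([0, 1])
        m = confusion_metrics(y, np.array([0.1, 0.2]), 0.9)
        assert np.isnan(m.precision)
        assert np.isnan(m.f_score)

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 10_000))
    def test_f_score_identity_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, 60)
        p = rng.random(60)
        m = confusion_metrics(y, p, 0.5)
        if not np.isnan(m.precision) and (m.precision + m.sensitivity) > 0:
            expected = 2 * m.precision * m.sensitivity / (m.precision + m.sensitivity)
            assert m.f_score == pytest.approx(expected, abs=1e-12)


class TestHoldoutSplit:
    def test_ten_subjects_yield_two_holdout(self):
        fog = {f"s{i}": float(i) for i in range(10)}
        split = holdout_split(fog, 0.2, seed=0)
        assert len(split.holdout_subjects) == 2
        assert set(split.train_subjects) | set(split.holdout_subjects) == set(fog)
        assert not set(split.train_subjects) & set(split.holdout_subjects)

    def test_degenerate_identical_percentages(self):
        fog = {f"s{i}": 5.0 for i in range(10)}
        split = holdout_split(fog, 0.2, seed=1)
        assert len(split.holdout_subjects) == 2

    def test_stratification_balances_holdout_fog(self):
        rng = np.random.default_rng(3)
        fog = {f"s{i}": float(v) for i, v in enumerate(rng.exponential(8, 40))}
        cohort_mean = np.mean(list(fog.values()))
        means = []
        for seed in range(200):
            split = holdout_split(fog, 0.2, seed=seed)
            means.append(np.mean([fog[s] for s in split.holdout_subjects]))
        assert abs(np.mean(means) - cohort_mean) <= 2.0

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValidationError):
            holdout_split({"a": 1.0, "b": 2.0}, 0.2, 0)


class TestGroupedKFold:
    def test_54_subjects_split_into_expected_fold_sizes(self):
        folds = grouped_kfold([f"s{i}" for i in range(54)], k=5, seed=0)
        sizes = sorted(len(f) for f in folds.folds)
        assert sizes == [10, 11, 11, 11, 11]

    def test_every_subject_in_exactly_one_fold(self):
        subjects = [f"s{i}" for i in range(17)]
        folds = grouped_kfold(subjects, k=5, seed=1)
        seen = [s for f in folds.folds for s in f]
        assert sorted(seen) == sorted(subjects)

    def test_train_and_validation_disjoint_per_fold(self):
        folds = grouped_kfold([f"s{i}" for i in range(12)], k=4, seed=2)
        for i in range(folds.k):
            assert not set(folds.folds[i]) & set(folds.train_subjects(i))

    def test_fewer_subjects_than_folds_rejected(self):
        with pytest.raises(ValidationError):
            grouped_kfold(["a", "b"], k=5, seed=0)


class TestCrossValidateAndAblation:
    def test_no_window_level_leakage(self, trembling_dataset):
        ds = trembling_dataset
        folds = grouped_kfold(ds.subjects(), k=4, seed=3)
        cv = cross_validate(ds, train_spectral_baseline, folds)
        assert len(cv.roc.aucs) == 4
        total_scored = sum(
            len(np.flatnonzero(np.isin(ds.subject_ids.astype(str), f)))
            for f in folds.folds
        )
        assert total_scored == len(ds)

    def test_ablation_reuses_folds_and_reports_channels(self, seven_sensor_dataset):
        ds = seven_sensor_dataset
        folds = grouped_kfold(ds.subjects(), k=3, seed=4)
        table, results = run_sensor_ablation(
            ds, train_spectral_baseline, folds, configs=("lower_legs", "lumbar")
        )
        assert list(table["n_channels"]) == [6, 3]
        for cv in results.values():
            assert cv.fold_assignment is folds

    def test_five_configurations_have_expected_channel_counts(self, seven_sensor_dataset):
        ds = seven_sensor_dataset
        folds = grouped_kfold(ds.subjects(), k=3, seed=5)
        table, _ = run_sensor_ablation(ds, train_spectral_baseline, folds)
        assert list(table["n_channels"]) == [21, 18, 6, 3, 3]

    def test_configuration_tie_breaks_toward_fewer_sensors(self):
        table = pd.DataFrame(
            {
                "configuration": ["six_legs_feet", "lower_legs", "lumbar"],
                "n_sensors": [6, 2, 1],
                "mean_auc": [0.87, 0.87, 0.79],
                "sd_auc": [0.05, 0.05, 0.04],
            }
        )
        assert select_configuration(table) == "lower_legs"

    def test_subject_fog_percent_reflects_annotations(self, trembling_dataset):
        pct = subject_fog_percent(trembling_dataset)
        assert set(pct) == set(trembling_dataset.subjects())
        assert all(0 <= v <= 100 for v in pct.values())
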