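"""Classifier families: class weights, MiniRocket internals, learnability,
determinism, and the shared probability contract."""

import numpy as np
import pytest

from conftest import make_dataset
from fogdetect.dataio import ValidationError
from fogdetect.evaluate import roc_auc
from fogdetect.models import (
    CNNConfig,
    InceptionConfig,
    MiniRocketConfig,
    MiniRocketTransform,
    compute_class_weights,
    fit_dilations,
    kernel_weight_matrix,
    train_cnn,
    train_inceptiontime,
    train_minirocket,
    train_spectral_baseline,
)
from fogdetect.models.minirocket import (
    KERNEL_LENGTH,
    N_KERNELS,
    dilated_convolution,
    ppv,
)


class TestClassWeights:
    def test_imbalanced_formula(self):
        y = np.array([0] * 90 + [1] * 10)
        w_neg, w_pos = compute_class_weights(y)
        assert w_neg == pytest.approx(100 / 180)
        assert w_pos == pytest.approx(5.0)

    def test_balanced_is_unit(self):
        y = np.array([0] * 50 + [1] * 50)
        assert compute_class_weights(y) == (1.0, 1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            compute_class_weights(np.zeros(10))

    def test_weighted_counts_equalized(self):
        y = np.array([0] * 70 + [1] * 30)
        w_neg, w_pos = compute_class_weights(y)
        assert w_neg * 70 == pytest.approx(w_pos * 30)


class TestMiniRocketTransform:
    def test_kernel_matrix_structure(self):
        W = kernel_weight_matrix()
        assert W.shape == (84, 9)
        assert np.all(np.sum(W == 2.0, axis=1) == 3)
        assert np.all(np.sum(W == -1.0, axis=1) == 6)
        np.testing.assert_allclose(W.sum(axis=1), 0.0)

    def test_feature_count_is_exact_multiple_of_kernels(self):
        dil, feats = fit_dilations(120, 10_000, 32)
        assert feats.sum() == 10_000 // 84 == 119
        assert feats.sum() * N_KERNELS == 9_996
        assert len(dil) <= 32
        # largest receptive field spans the window
        assert (KERNEL_LENGTH - 1) * dil[-1] <= 120 - 1

    def test_transform_output_shape_and_range(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 120, 3))
        tr = MiniRocketTransform(MiniRocketConfig(seed=1))
        F = tr.fit_transform(X)
        assert F.shape == (40, 9_996)
        assert F.min() >= 0.0 and F.max() <= 1.0

    def test_ppv_matches_brute_force_on_toy_series(self):
        """Hand-enumerated PPV for one kernel/dilation/bias on a 12-sample
        series equals the transform's column."""
        rng = np.random.default_rng(3)
        X = rng.normal(size=(5, 12, 1))
        tr = MiniRocketTransform(MiniRocketConfig(feature_budget=84 * 4, seed=2))
        tr.fit(X)
        ki, di = 10, 0
        dilation = int(tr.dilations[di])
        chans = tr.channel_set(ki, di)
        biases = tr.biases[(ki, di)]
        col = tr._column(ki, di)
        F = tr.transform(X)
        w = tr.weights[ki]
        for n in range(5):
            series = X[n, :, chans[0]] if len(chans) == 1 else X[n][:, chans].sum(1)
            pad = (KERNEL_LENGTH // 2) * dilation
            padded = np.concatenate([np.zeros(pad), series, np.zeros(pad)])
            conv = np.array(
                [
                    sum(w[j] * padded[t + j * dilation] for j in range(KERNEL_LENGTH))
                    for t in range(12)
                ]
            )
            for bi, b in enumerate(biases):
                frac = np.mean(conv > b)
                # feature matrix is float32; compare at that precision
                assert F[n, col + bi] == pytest.approx(frac, abs=1e-6)

    def test_dilated_convolution_helper_agrees_with_loops(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(3, 20))
        w = kernel_weight_matrix()[17]
        out = dilated_convolution(x, w, 2)
        pad = 4 * 2
        for n in range(3):
            padded = np.concatenate([np.zeros(pad), x[n], np.zeros(pad)])
            brute = [
                sum(w[j] * padded[t + 2 * j] for j in range(9)) for t in range(20)
            ]
            np.testing.assert_allclose(out[n], brute, atol=1e-12)

    def test_all_zero_windows_with_positive_bias_give_zero_features(self):
        assert ppv(np.zeros((4, 12)), 0.5).tolist() == [0.0] * 4

    def test_transform_before_fit_is_an_error(self):
        tr = MiniRocketTransform()
        with pytest.raises(ValidationError):
            tr.transform(np.zeros((2, 120, 1)))

    def test_amplitude_scaling_invariance_with_refit_biases(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 120, 2))
        cfg = MiniRocketConfig(feature_budget=84 * 8, seed=6)
        F1 = MiniRocketTransform(cfg).fit_transform(X)
        F2 = MiniRocketTransform(cfg).fit_transform(3.7 * X)
        np.testing.assert_allclose(F1, F2, atol=1e-9)


class TestMiniRocketModel:
    def test_learns_separable_cohort(self, train_val_split):
        train, val = train_val_split
        model = train_minirocket(train, MiniRocketConfig(seed=1))
        assert model.coef_.shape == (model.transformer.n_features,)
        _, _, auc = roc_auc(val.y(), model.predict_dataset(val))
        assert auc >= 0.85

    def test_shuffled_labels_give_null_auc(self, train_val_split):
        """Permuting labels across the whole cohort destroys the label-signal
        coupling, so validation AUC collapses to chance."""
        train, val = train_val_split
        rng = np.random.default_rng(0)
        shuffled_train = train.select(np.arange(len(train)))
        shuffled_train.labels = shuffled_train.labels[rng.permutation(len(train))]
        shuffled_val_y = val.y()[rng.permutation(len(val))]
        model = train_minirocket(shuffled_train, MiniRocketConfig(seed=1))
        _, _, auc = roc_auc(shuffled_val_y, model.predict_dataset(val))
        assert 0.4 <= auc <= 0.6


class TestCNN:
    def test_learns_separable_cohort_and_is_deterministic(self, train_val_split):
        train, val = train_val_split
        cfg = CNNConfig(epochs=8, seed=2)
        m1 = train_cnn(train, cfg)
        p1 = m1.predict_dataset(val)
        _, _, auc = roc_auc(val.y(), p1)
        assert auc >= 0.90
        m2 = train_cnn(train, cfg)
        np.testing.assert_array_equal(p1, m2.predict_dataset(val))

    def test_batch_size_invariant_prediction(self, train_val_split):
        train, val = train_val_split
        m = train_cnn(train, CNNConfig(epochs=1, seed=3))
        few = val.X[:7]
        whole = m.predict_proba(val.X, val.channel_names)[:7]
        one_by_one = np.concatenate(
            [m.predict_proba(few[i : i + 1]) for i in range(7)]
        )
        np.testing.assert_allclose(one_by_one, whole, atol=1e-6)

    def test_channel_mismatch_rejected(self, train_val_split):
        train, _ = train_val_split
        m = train_cnn(train, CNNConfig(epochs=1, seed=4))
        with pytest.raises(ValidationError, match="channel"):
            m.predict_proba(np.zeros((2, 120, 9)))
        with pytest.raises(ValidationError, match="mismatch"):
            m.predict_proba(
                np.zeros((2, 120, 6)),
                tuple(f"foot_left_{a}" for a in "xyz")
                + tuple(f"foot_right_{a}" for a in "xyz"),
            )

    def test_probabilities_bounded(self, train_val_split):
        train, val = train_val_split
        m = train_cnn(train, CNNConfig(epochs=1, seed=5))
        p = m.predict_dataset(val)
        assert np.all((p >= 0) & (p <= 1))


class TestInceptionTime:
    SMALL = dict(bottleneck=8, filters=8, epochs=4, seed=6)

    def test_learns_separable_cohort(self, train_val_split):
        train, val = train_val_split
        sub = train.select(np.arange(0, len(train), 2))  # thin for speed
        model = train_inceptiontime(sub, InceptionConfig(n_ensemble=2, **self.SMALL))
        _, _, auc = roc_auc(val.y(), model.predict_dataset(val))
        assert auc >= 0.85

    def test_single_network_ensemble_is_valid(self, train_val_split):
        train, val = train_val_split
        sub = train.select(np.arange(0, len(train), 8))
        model = train_inceptiontime(
            sub, InceptionConfig(n_ensemble=1, epochs=1, bottleneck=4, filters=4, seed=7)
        )
        p = model.predict_dataset(val)
        assert np.all((p >= 0) & (p <= 1))

    def test_ensemble_probability_is_mean_of_members(self, train_val_split):
        train, val = train_val_split
        sub = train.select(np.arange(0, len(train), 8))
        model = train_inceptiontime(
            sub, InceptionConfig(n_ensemble=3, epochs=1, bottleneck=4, filters=4, seed=8)
        )
        X = val.X[:10]
        members = model.member_probabilities(X)
        np.testing.assert_allclose(
            model.predict_proba(X, val.channel_names), members.mean(axis=0), atol=1e-12
        )


class TestSpectralBaseline:
    def test_separates_trembling_fog(self, train_val_split):
        train, val = train_val_split
        model = train_spectral_baseline(train)
        _, _, auc = roc_auc(val.y(), model.predict_dataset(val))
        assert auc >= 0.90

    def test_mean_probability_ordering(self, train_val_split):
        train, val = train_val_split
        model = train_spectral_baseline(train)
        p = model.predict_dataset(val)
        y = val.y()
        assert p[y == 1].mean() > p[y == 0].mean()


def test_single_class_training_rejected():
    rng = np.random.default_rng(1)
    ds = make_dataset(rng.normal(size=(20, 120, 3)), np.zeros(20))
    with pytest.raises(ValidationError):
        train_cnn(ds, CNNConfig(epochs=1))
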