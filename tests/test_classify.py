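import numpy as np
import pytest
from scipy import stats

from voxtex.classify import (
    CVConfig,
    count_planned_fits,
    external_validate,
    metrics,
    nested_cv,
    predict,
    select_features,
    stratified_folds,
    train_mlp,
    welch_t,
    TrainedMLP,
)


def _toy_separable(n=30, rng=None):
    rng = rng or np.random.default_rng(0)
    y = np.repeat([1, -1], n // 2)
    X = rng.standard_normal((n, 2))
    X[:, 0] += 3.0 * y
    return X, y


def _make_linear_model(w, mean=None, std=None):
    w = np.asarray(w, dtype=float).reshape(-1, 1)
    n = w.shape[0]
    return TrainedMLP(
        weights=[w],
        biases=[np.zeros(1)],
        selected_features=np.arange(n),
        feature_mean=np.zeros(n) if mean is None else mean,
        feature_std=np.ones(n) if std is None else std,
        l2_lambda=0.0,
    )


class TestWelchT:
    def test_matches_scipy_oracle(self, rng):
        X = rng.standard_normal((24, 40))
        y = np.repeat([1, -1], 12)
        ours = welch_t(X, y)
        ref = stats.ttest_ind(X[y > 0], X[y < 0], equal_var=False).statistic
        np.testing.assert_allclose(ours, ref, atol=1e-12)

    def test_zero_variance_columns_get_zero(self):
        X = np.ones((10, 3))
        X[:, 1] = np.arange(10)
        y = np.repeat([1, -1], 5)
        t = welch_t(X, y)
        assert t[0] == 0.0 and t[2] == 0.0

    def test_too_few_samples_rejected(self):
        X = np.zeros((3, 2))
        y = np.array([1, 1, -1])
        with pytest.raises(ValueError):
            welch_t(X, y)


class TestSelectFeatures:
    def test_dominant_column_first(self, rng):
        X = rng.standard_normal((20, 10))
        y = np.repeat([1, -1], 10)
        X[:, 7] = 10.0 * y + 0.01 * rng.standard_normal(20)
        sel = select_features(X, y, 3)
        assert sel[0] == 7

    def test_k_equals_n_is_permutation(self, rng):
        X = rng.standard_normal((20, 15))
        y = np.repeat([1, -1], 10)
        sel = select_features(X, y, 15)
        assert sorted(sel) == list(range(15))

    def test_matches_per_column_oracle(self, rng):
        X = rng.standard_normal((30, 50))
        y = np.repeat([1, -1], 15)
        sel = set(select_features(X, y, 20))
        ref_t = np.abs(
            stats.ttest_ind(X[y > 0], X[y < 0], equal_var=False).statistic
        )
        ref = set(np.argsort(-ref_t, kind="stable")[:20])
        assert sel == ref

    def test_k_too_large_rejected(self, rng):
        X = rng.standard_normal((10, 5))
        y = np.repeat([1, -1], 5)
        with pytest.raises(ValueError):
            select_features(X, y, 6)

    def test_tie_break_by_index(self):
        X = np.zeros((10, 4))
        y = np.repeat([1, -1], 5)
        sel = select_features(X, y, 2)
        assert list(sel) == [0, 1]


class TestTrainMlp:
    def test_separable_toy_reaches_perfect_training_accuracy(self):
        X, y = _toy_separable()
        m = train_mlp(X, y, CVConfig(epochs_max=200), np.random.default_rng(1))
        _, pred = predict(m, X)
        assert np.all(pred == y)

    def test_architecture(self):
        X, y = _toy_separable()
        m = train_mlp(X, y, CVConfig(epochs_max=5), np.random.default_rng(0))
        assert m.layer_sizes == [2, 2, 2, 2, 2, 2, 1]

    def test_epochs_max_honored(self):
        X, y = _toy_separable()
        cfg = CVConfig(epochs_max=17)
        m = train_mlp(X, y, cfg, np.random.default_rng(0))
        assert m.epochs_run <= 17

    def test_accepted_losses_non_increasing(self):
        X, y = _toy_separable(n=40, rng=np.random.default_rng(3))
        m = train_mlp(X, y, CVConfig(epochs_max=100), np.random.default_rng(2))
        assert np.all(np.diff(m.loss_history) <= 0)

    def test_bad_labels_rejected(self):
        X = np.zeros((4, 2))
        with pytest.raises(ValueError):
            train_mlp(X, np.array([0, 1, 1, 0]), CVConfig())

    def test_nonfinite_input_rejected(self):
        X = np.full((4, 2), np.nan)
        y = np.array([1, 1, -1, -1])
        with pytest.raises(ValueError):
            train_mlp(X, y, CVConfig())

    def test_deterministic_given_rng(self):
        X, y = _toy_separable()
        a = train_mlp(X, y, CVConfig(epochs_max=30), np.random.default_rng(5))
        b = train_mlp(X, y, CVConfig(epochs_max=30), np.random.default_rng(5))
        for wa, wb in zip(a.weights, b.weights):
            np.testing.assert_array_equal(wa, wb)


class TestPredict:
    def test_zero_model_all_positive(self):
        m = TrainedMLP(
            weights=[np.zeros((3, 2))] + [np.zeros((2, 2))] * 4 + [np.zeros((2, 1))],
            biases=[np.zeros(2)] * 5 + [np.zeros(1)],
            selected_features=np.arange(3),
            feature_mean=np.zeros(3),
            feature_std=np.ones(3),
            l2_lambda=0.0,
        )
        scores, labels = predict(m, np.random.default_rng(0).standard_normal((5, 3)))
        assert np.all(scores == 0)
        assert np.all(labels == 1)  # tie rule: score 0 → positive class

    def test_dimension_mismatch_rejected(self):
        m = _make_linear_model([1.0, 2.0])
        with pytest.raises(ValueError):
            predict(m, np.zeros((3, 5)))

    def test_small_weight_linearization(self, rng):
        """Deep tanh net with tiny weights ≈ product of its linear maps."""
        eps = 1e-4
        ws = [rng.standard_normal((4, 2)) * eps]
        ws += [rng.standard_normal((2, 2)) * eps for _ in range(4)]
        ws += [rng.standard_normal((2, 1)) * eps]
        m = TrainedMLP(
            weights=ws,
            biases=[np.zeros(2)] * 5 + [np.zeros(1)],
            selected_features=np.arange(4),
            feature_mean=np.zeros(4),
            feature_std=np.ones(4),
            l2_lambda=0.0,
        )
        X = rng.standard_normal((6, 4))
        lin = X.copy()
        for w in ws:
            lin = lin @ w
        scores, _ = predict(m, X)
        np.testing.assert_allclose(scores, lin[:, 0], rtol=1e-6, atol=1e-18)

    def test_training_predictions_reproduce_labels(self):
        X, y = _toy_separable()
        m = train_mlp(X, y, CVConfig(epochs_max=200), np.random.default_rng(7))
        _, pred = predict(m, X)
        assert np.array_equal(pred, y)


class TestMetrics:
    def test_chance_symmetry(self):
        bacc, _, _ = metrics(tp=5, fn=5, tn=3, fp=3)
        assert bacc == pytest.approx(0.5)

    def test_perfect(self):
        bacc, sens, spec = metrics(tp=10, fn=0, tn=7, fp=0)
        assert (bacc, sens, spec) == (1.0, 1.0, 1.0)

    def test_direct_arithmetic(self):
        bacc, sens, spec = metrics(tp=7, fn=3, tn=9, fp=1)
        assert sens == pytest.approx(0.7)
        assert spec == pytest.approx(0.9)
        assert bacc == pytest.approx(0.8)

    def test_absent_class_is_nan(self):
        bacc, sens, spec = metrics(tp=0, fn=0, tn=5, fp=1)
        assert np.isnan(sens) and np.isnan(bacc)
        assert spec == pytest.approx(5 / 6)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            metrics(-1, 0, 0, 1)


class TestStratifiedFolds:
    def test_folds_cover_everything(self, rng):
        y = np.repeat([1, -1], 10)
        folds = stratified_folds(y, 5, rng)
        assert sorted(np.concatenate(folds)) == list(range(20))
        for f in folds:
            assert (y[f] > 0).any() and (y[f] < 0).any()

    def test_too_few_samples_rejected(self, rng):
        y = np.array([1, 1, -1, -1, -1])
        with pytest.raises(ValueError):
            stratified_folds(y, 3, rng)


def _small_cv_config(**kw):
    defaults = dict(
        outer_folds=3, inner_folds=3, outer_reps=1, inner_reps=1,
        k_features=5, epochs_max=30, seed=0,
    )
    defaults.update(kw)
    return CVConfig(**defaults)


class TestNestedCV:
    def test_planned_fit_count_full_profile(self):
        assert count_planned_fits(CVConfig()) == 10 * 10 * 10 * 10 == 10_000

    def test_planned_fit_count_small_profile(self):
        assert count_planned_fits(_small_cv_config()) == 9

    def test_model_and_inner_fit_bookkeeping(self, rng):
        X = rng.standard_normal((24, 20))
        y = np.repeat([1, -1], 12)
        cfg = _small_cv_config(outer_reps=2)
        result = nested_cv(X, y, cfg)
        assert len(result.models) == 2 * 3
        assert len(result.inner_val_acc) == count_planned_fits(cfg)
        assert len(result.folds) == 2 * 3

    def test_strong_signal_recovered(self, rng):
        y = np.repeat([1, -1], 15)
        X = rng.standard_normal((30, 30))
        X[:, :5] += 3.0 * y[:, None]
        result = nested_cv(X, y, _small_cv_config())
        assert result.balanced_accuracy >= 0.9

    def test_permutation_null_at_chance(self):
        """Mean CV balanced accuracy within 3 SE of 0.5 over permuted labels."""
        rng = np.random.default_rng(42)
        X = rng.standard_normal((24, 30))
        baccs = []
        for i in range(10):
            y = rng.permutation(np.repeat([1, -1], 12))
            result = nested_cv(X, y, _small_cv_config(seed=i))
            baccs.append(result.balanced_accuracy)
        se = np.std(baccs, ddof=1) / np.sqrt(len(baccs))
        assert abs(np.mean(baccs) - 0.5) < 3 * max(se, 1e-3)

    def test_seeded_determinism(self, rng):
        X = rng.standard_normal((24, 15))
        y = np.repeat([1, -1], 12)
        cfg = _small_cv_config(seed=3)
        a = nested_cv(X, y, cfg)
        b = nested_cv(X, y, cfg)
        assert [(f.tp, f.fn, f.tn, f.fp) for f in a.folds] == [
            (f.tp, f.fn, f.tn, f.fp) for f in b.folds
        ]
        for ma, mb in zip(a.models, b.models):
            np.testing.assert_array_equal(ma.selected_features, mb.selected_features)
            for wa, wb in zip(ma.weights, mb.weights):
                np.testing.assert_array_equal(wa, wb)

    def test_selection_from_training_partition_only(self, rng):
        """Each outer model's features must be computable without its hold-out."""
        X = rng.standard_normal((24, 20))
        y = np.repeat([1, -1], 12)
        result = nested_cv(X, y, _small_cv_config())
        for fold, model in zip(result.folds, result.models):
            assert model.selected_features.max() < X.shape[1]
            # hold-out rows cannot influence selection: perturb them wildly
            X2 = X.copy()
            X2[fold.test_indices] += 100.0
            # rerun only this fold's consensus path by rerunning the whole CV
            # with identical seed; training rows unchanged → same selection
        result2 = nested_cv(X, y, _small_cv_config())
        for ma, mb in zip(result.models, result2.models):
            np.testing.assert_array_equal(ma.selected_features, mb.selected_features)

    def test_balanced_accuracy_identity(self, rng):
        X = rng.standard_normal((24, 10))
        y = np.repeat([1, -1], 12)
        result = nested_cv(X, y, _small_cv_config())
        for f in result.folds:
            bacc, sens, spec = metrics(f.tp, f.fn, f.tn, f.fp)
            assert bacc == pytest.approx((sens + spec) / 2.0)


class TestExternalValidate:
    def test_counts_sum_to_n_external(self, rng):
        X = rng.standard_normal((24, 10))
        y = np.repeat([1, -1], 12)
        result = nested_cv(X, y, _small_cv_config())
        X_ext = rng.standard_normal((15, 10))
        out = external_validate(result, X_ext)
        assert out["n_positive"] + out["n_negative"] == 15

    def test_single_model_single_subject(self):
        m = _make_linear_model([2.0])
        result_like = type("R", (), {"models": [m]})()
        out = external_validate(result_like, np.array([[3.0]]))
        assert out["n_positive"] == 1 and out["n_negative"] == 0
        assert out["vote_fraction_positive"][0] == 1.0

    def test_external_set_matching_positive_class(self, rng):
        y = np.repeat([1, -1], 15)
        X = rng.standard_normal((30, 20))
        X[:, :5] += 3.0 * y[:, None]
        result = nested_cv(X, y, _small_cv_config())
        X_ext = rng.standard_normal((10, 20))
        X_ext[:, :5] += 3.0  # drawn from the positive class's distribution
        out = external_validate(result, X_ext)
        assert out["n_positive"] >= 8
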