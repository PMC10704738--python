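import numpy as np
import pytest

from rosscreen.augment import SmoteConfig
from rosscreen.ros_model import (
    DnnConfig,
    RfConfig,
    evaluate,
    holdout_generalization,
    predict,
    split_indices,
    split_train_test,
    train,
)
from rosscreen.synthetic_data import SyntheticSpec, generate_library, planted_truth


class TestSplit:
    def test_paper_sizes(self):
        tr, te = split_indices(19280, 0.10, seed=0)
        assert len(te) == 1928 and len(tr) == 17352

    def test_two_point_half_split(self):
        tr, te = split_indices(2, 0.5, seed=1)
        assert len(tr) == len(te) == 1

    def test_partition_is_disjoint_and_exhaustive(self):
        for seed in range(100):
            tr, te = split_indices(137, 0.2, seed=seed)
            assert set(tr) | set(te) == set(range(137))
            assert set(tr) & set(te) == set()

    def test_degenerate_fraction_rejected(self):
        with pytest.raises(ValueError):
            split_indices(10, 0.01, seed=0)

    def test_xy_wrapper(self, rng):
        X = rng.normal(size=(50, 3))
        y = rng.normal(size=50)
        Xtr, Xte, ytr, yte = split_train_test(X, y, 0.2, seed=3)
        assert len(Xte) == 10 and len(Xtr) == 40
        assert len(ytr) == 40 and len(yte) == 10


class TestEvaluate:
    def test_worked_example(self):
        m = evaluate(np.array([1.0, 2, 3]), np.array([2.0, 2, 2]), threshold=10)
        assert m.rmse == pytest.approx(np.sqrt(2 / 3))

    def test_perfect_prediction(self):
        y = np.array([1.0, 5.0, 4.7, 3.0])
        m = evaluate(y, y, threshold=4.67)
        assert m.rmse == 0.0
        assert m.precision == 1.0 and m.recall == 1.0 and m.f_measure == 1.0

    def test_confusion_counts(self):
        # TP=2, FP=1, FN=0 -> precision 2/3, recall 1, F 0.8
        y_true = np.array([5.0, 5.0, 1.0, 1.0])
        y_pred = np.array([5.0, 5.0, 5.0, 1.0])
        m = evaluate(y_true, y_pred, threshold=4.67)
        assert m.counts == {"tp": 2, "fp": 1, "fn": 0, "tn": 1}
        assert m.precision == pytest.approx(2 / 3)
        assert m.recall == 1.0
        assert m.f_measure == pytest.approx(0.8)

    def test_undefined_ratios_flagged_null(self):
        y = np.array([1.0, 2.0])  # no actual or predicted positives
        m = evaluate(y, y, threshold=4.67)
        assert m.precision is None and m.recall is None and m.f_measure is None

    def test_harmonic_mean_identity(self, rng):
        y = rng.uniform(1, 6, size=200)
        p = y + rng.normal(scale=0.5, size=200)
        m = evaluate(y, p)
        if m.f_measure is not None:
            assert m.f_measure == pytest.approx(
                2 * m.precision * m.recall / (m.precision + m.recall), abs=1e-9
            )

    def test_rmse_order_invariant_and_scaling(self, rng):
        y = rng.uniform(0, 5, size=100)
        p = y + rng.normal(size=100)
        perm = rng.permutation(100)
        assert evaluate(y, p).rmse == pytest.approx(evaluate(y[perm], p[perm]).rmse)
        assert evaluate(3 * y, 3 * p).rmse == pytest.approx(3 * evaluate(y, p).rmse)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluate(np.array([1.0]), np.array([1.0, 2.0]))


class TestTrainPredict:
    def test_rf_single_stump_predicts_leaf_means(self):
        X = np.array([[0.0], [1.0]])
        y = np.array([2.0, 4.0])
        model = train(X, y, RfConfig(n_trees=1, max_depth=1, seed=0))
        np.testing.assert_allclose(predict(model, X), y)

    def test_noiseless_linear_signal_learned(self):
        """With zero noise a network fits the planted signal tightly."""
        rng = np.random.default_rng(0)
        X = rng.normal(size=(600, 5))
        y = X @ np.array([1.0, -0.5, 0.3, 0.0, 0.0])
        model = train(X, y, DnnConfig(epochs=100, seed=0))
        rmse = float(np.sqrt(np.mean((predict(model, X) - y) ** 2)))
        assert rmse < 0.05

    def test_duplicated_row_identical_prediction(self, rng):
        X = rng.normal(size=(50, 4))
        y = rng.normal(size=50)
        model = train(X, y, RfConfig(seed=1))
        X2 = np.vstack([X[0], X[0]])
        p = predict(model, X2)
        assert p[0] == p[1]

    def test_chunked_vs_whole_prediction(self, rng):
        X = rng.normal(size=(200, 6))
        y = rng.normal(size=200)
        model = train(X, y, DnnConfig(epochs=10, seed=0))
        whole = predict(model, X)
        parts = np.concatenate([predict(model, X[i : i + 37]) for i in range(0, 200, 37)])
        np.testing.assert_allclose(whole, parts, atol=1e-6)

    def test_feature_mismatch_rejected(self, rng):
        X = rng.normal(size=(30, 3))
        model = train(X, rng.normal(size=30), RfConfig(), selected_features=["a", "b", "c"])
        with pytest.raises(ValueError, match="feature mismatch"):
            predict(model, X, feature_names=["a", "b", "z"])
        with pytest.raises(ValueError):
            predict(model, X[:, :2])

    def test_predictions_track_planted_truth(self, small_spec, small_library):
        from scipy.stats import spearmanr

        lib = small_library.training_view()
        names, _ = planted_truth(small_spec, small_library)
        sub = lib.select_features(names)
        tr, te = split_indices(len(sub), 0.25, seed=0)
        model = train(sub.X[tr], sub.log_ros[tr], DnnConfig(epochs=50, seed=0),
                      selected_features=names)
        rho = spearmanr(predict(model, sub.X[te]), sub.log_ros[te]).statistic
        assert rho > 0.5


@pytest.fixture(scope="module")
def holdout_result():
    spec = SyntheticSpec(n_compounds=1500, n_features=30, n_informative=5,
                         modulator_fraction=0.06, noise_sd=0.1, seed=21)
    lib = generate_library(spec)
    res = holdout_generalization(
        lib, DnnConfig(epochs=60, seed=0), SmoteConfig(seed=42), seed=4
    )
    return lib, res


class TestHoldoutGeneralization:
    def test_holdout_disjoint_from_smote_parents(self, holdout_result):
        _, res = holdout_result
        assert set(res.holdout_indices) & set(res.smote_parent_indices) == set()

    def test_strong_signal_beats_base_rate(self, holdout_result):
        lib, res = holdout_result
        base = lib.labels.mean()
        assert res.metrics.precision is not None
        assert res.metrics.precision > base

    def test_holdout_sizes_stratified(self, holdout_result):
        lib, res = holdout_result
        labels = lib.labels
        n_pos = int(round(labels.sum() * 0.10))
        n_neg = int(round((~labels).sum() * 0.10))
        assert len(res.holdout_indices) == n_pos + n_neg

    def test_emptying_class_rejected(self):
        spec = SyntheticSpec(n_compounds=300, n_features=10, n_informative=3,
                             modulator_fraction=0.02, seed=1)
        lib = generate_library(spec)
        with pytest.raises(ValueError, match="empty"):
            holdout_generalization(lib, RfConfig(), holdout_fraction=0.01, seed=0)
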