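"""Fingerprints, feature selection, model tuning and performance metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from moldesign.qsar import (
    ActivityModel,
    FingerprintSpec,
    classification_metrics,
    compute_fingerprint,
    fingerprint_matrix,
    mutual_information,
    regression_metrics,
    select_features,
    tune_and_fit,
)


class TestFingerprints:
    @pytest.mark.parametrize("kind", ["rdkit_topological", "ecfp4", "avalon", "morgan2048"])
    def test_deterministic_and_sized(self, kind):
        spec = FingerprintSpec(kind=kind)
        fp1 = compute_fingerprint("c1ccccc1CCN", spec)
        fp2 = compute_fingerprint("NCCc1ccccc1", spec)  # same molecule, respelled
        assert fp1.shape == (spec.n_bits,)
        np.testing.assert_array_equal(fp1, fp2)
        assert set(np.unique(fp1)) <= {0, 1}

    def test_distinct_molecules_share_fewer_bits(self):
        spec = FingerprintSpec("ecfp4")
        ethanol = compute_fingerprint("CCO", spec)
        octanol = compute_fingerprint("CCCCCCCCO", spec)
        self_shared = int((ethanol & ethanol).sum())
        cross_shared = int((ethanol & octanol).sum())
        assert cross_shared < self_shared

    def test_invalid_molecule_errors(self):
        with pytest.raises(ValueError):
            compute_fingerprint("((")


class TestMutualInformation:
    def test_perfectly_matched_balanced_pair_is_ln2(self):
        assert mutual_information([0, 1] * 10, [0, 1] * 10) == pytest.approx(np.log(2))

    def test_independent_empirical_joint_is_zero(self):
        assert mutual_information([0, 0, 1, 1], [0, 1, 0, 1]) == pytest.approx(0.0)

    @given(st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1)), min_size=1, max_size=60))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_symmetric_and_nonnegative(self, pairs):
        z = [p[0] for p in pairs]
        y = [p[1] for p in pairs]
        assert mutual_information(z, y) == pytest.approx(mutual_information(y, z))
        assert mutual_information(z, y) >= 0.0


class TestSelectFeatures:
    def test_label_copy_column_always_selected_by_mi(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 100)
        X = rng.integers(0, 2, (100, 20))
        X[:, 7] = y
        cols = select_features(X, y, method="mi", top_k=5)
        assert 7 in cols

    def test_constant_columns_never_selected_by_mi(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 60)
        X = rng.integers(0, 2, (60, 10))
        X[:, 3] = 1
        cols = select_features(X, y, method="mi", top_k=10)
        assert 3 not in cols

    def test_lasso_stronger_penalty_selects_fewer(self):
        rng = np.random.default_rng(2)
        X = rng.integers(0, 2, (80, 30)).astype(float)
        y = rng.normal(size=80)
        few = select_features(X, y, method="lasso", lasso_alphas=[0.1])
        many = select_features(X, y, method="lasso", lasso_alphas=[0.001])
        assert len(few) < len(many)

    def test_all_zero_matrix_errors(self):
        with pytest.raises(ValueError):
            select_features(np.zeros((10, 4)), np.zeros(10))


class TestMetrics:
    def test_confusion_hand_case(self):
        # TP=2, TN=3, FP=1, FN=0
        y_true = [1, 1, 0, 0, 0, 0]
        y_pred = [1, 1, 1, 0, 0, 0]
        acc, f1 = classification_metrics(y_pred, y_true)
        assert acc == pytest.approx(5 / 6, abs=1e-9)
        assert f1 == pytest.approx(0.8, abs=1e-9)

    def test_perfect_prediction(self):
        acc, f1 = classification_metrics([1, 0, 1], [1, 0, 1])
        assert (acc, f1) == (1.0, 1.0)

    def test_matches_sklearn_on_random_vectors(self):
        from sklearn.metrics import accuracy_score, f1_score

        rng = np.random.default_rng(3)
        y_true = rng.integers(0, 2, 50)
        y_pred = rng.integers(0, 2, 50)
        acc, f1 = classification_metrics(y_pred, y_true)
        assert acc == pytest.approx(accuracy_score(y_true, y_pred))
        assert f1 == pytest.approx(f1_score(y_true, y_pred))

    def test_regression_hand_case(self):
        mre, mae, rmse = regression_metrics([1.1, 1.8], [1.0, 2.0])
        assert mre == pytest.approx(0.1, abs=1e-9)
        assert mae == pytest.approx(0.15, abs=1e-9)
        assert rmse == pytest.approx(np.sqrt(0.025), abs=1e-9)

    def test_identical_vectors_are_zero(self):
        assert regression_metrics([1.0, 2.0], [1.0, 2.0]) == (0.0, 0.0, 0.0)

    def test_rmse_at_least_mae_random(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=100) + 5
        yhat = y + rng.normal(size=100)
        mre, mae, rmse = regression_metrics(yhat, y)
        assert rmse >= mae
        # independent recomputation
        assert mae == pytest.approx(np.abs(yhat - y).mean())
        assert rmse == pytest.approx(np.sqrt(((yhat - y) ** 2).mean()))

    def test_zero_in_targets_rejected_for_mre(self):
        with pytest.raises(ValueError, match="MRE"):
            regression_metrics([1.0], [0.0])

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            classification_metrics([], [])


class TestTuneAndFit:
    def _separable(self, n=120, seed=0):
        rng = np.random.default_rng(seed)
        X = np.zeros((n, 30), dtype=int)
        y = np.repeat([0, 1], n // 2)
        X[y == 0, :10] = rng.integers(0, 2, (n // 2, 10))
        X[y == 1, 20:] = rng.integers(0, 2, (n // 2, 10))
        X[y == 1, 25] = 1
        X[y == 0, 5] = 1
        return X, y

    def test_separable_data_scores_high(self):
        X, y = self._separable()
        _, report, _ = tune_and_fit(X, y, family="svm", task="classify", n_trials=5, seed=0)
        assert report.mean_metrics["accuracy"] >= 0.95

    def test_same_seed_reproduces_hyperparameters(self):
        X, y = self._separable()
        reports = [
            tune_and_fit(X, y, family="gbdt", task="classify", n_trials=4, seed=7)[1]
            for _ in range(2)
        ]
        assert reports[0].chosen_params == reports[1].chosen_params
        assert reports[0].mean_metrics == reports[1].mean_metrics

    def test_single_class_labels_rejected(self):
        X, _ = self._separable()
        with pytest.raises(ValueError):
            tune_and_fit(X, np.zeros(len(X)), family="svm", task="classify")

    def test_fold_partition_property(self):
        from sklearn.model_selection import KFold

        folds = list(KFold(5, shuffle=True, random_state=0).split(np.zeros((103, 1))))
        all_test = np.concatenate([te for _, te in folds])
        assert sorted(all_test) == list(range(103))
        sizes = [len(te) for _, te in folds]
        assert max(sizes) - min(sizes) <= 1


class TestActivityModel:
    def test_fit_predict_round_trip(self):
        from moldesign.fixtures import generate_smiles_corpus

        plain = generate_smiles_corpus(40, seed=41, marker_fraction=0.0)
        marked = generate_smiles_corpus(40, seed=42, marker_fraction=1.0)
        smiles = plain + marked
        y = np.array([0] * 40 + [1] * 40)
        model = ActivityModel(family="svm", n_trials=3, seed=0).fit(smiles, y)
        preds = model.predict(smiles)
        assert preds.shape == (80,)
        assert (preds == y).mean() >= 0.9
        assert model.cv_report_.mean_metrics["accuracy"] > 0.8
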