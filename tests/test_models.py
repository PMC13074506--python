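import numpy as np
import pytest

from teaspec.errors import ConfigurationError, InputError
from teaspec.models import (
    CNNArchitectureConfig,
    CVConfig,
    fit_predict_cnn,
    fit_predict_gpr,
    fit_predict_xgb,
    permutation_importance,
)

from conftest import correlated_index_matrix


class TestCVConfig:
    def test_folds_partition_every_sample_exactly_once(self):
        cv = CVConfig(10, seed=3)
        folds = cv.folds(97)
        seen = np.concatenate([val for _, val in folds])
        assert sorted(seen) == list(range(97))
        for train, val in folds:
            assert np.intersect1d(train, val).size == 0
            assert len(train) + len(val) == 97

    def test_too_few_samples_rejected(self):
        with pytest.raises(InputError):
            CVConfig(10).folds(5)


class TestXGB:
    def test_recovers_exact_linear_function_of_one_index(self, rng):
        n = 200
        x = rng.random((n, 20))
        y = 3.0 + 5.0 * x[:, 7]  # noise-free
        report = fit_predict_xgb(x, y, CVConfig(10, seed=1))
        assert report.metrics.r2 >= 0.95
        assert report.metrics.n == n

    def test_no_signal_after_target_permutation(self, rng):
        x, y = correlated_index_matrix(150, rng)
        report = fit_predict_xgb(x, rng.permutation(y), CVConfig(10, seed=2))
        assert report.metrics.r2 <= 0.1

    def test_same_seed_gives_identical_report(self, rng):
        x, y = correlated_index_matrix(60, rng, n_cols=20)
        a = fit_predict_xgb(x, y, CVConfig(5, seed=4))
        b = fit_predict_xgb(x, y, CVConfig(5, seed=4))
        np.testing.assert_array_equal(a.predictions, b.predictions)

    def test_non_finite_inputs_rejected(self, rng):
        x, y = correlated_index_matrix(30, rng, n_cols=5)
        x[3, 2] = np.nan
        with pytest.raises(InputError):
            fit_predict_xgb(x, y, CVConfig(3))


class TestGPR:
    def test_recovers_noise_free_linear_target(self, rng):
        n = 200
        x = rng.random((n, 10))
        y = 2.0 - 4.0 * x[:, 3]
        report = fit_predict_gpr(x, y, CVConfig(10, seed=1))
        assert report.metrics.r2 >= 0.95

    def test_predictions_carry_original_units(self, rng):
        x, y = correlated_index_matrix(80, rng, n_cols=15)
        a = fit_predict_gpr(x, y, CVConfig(5, seed=2))
        b = fit_predict_gpr(x, y + 100.0, CVConfig(5, seed=2))
        np.testing.assert_allclose(b.predictions, a.predictions + 100.0, atol=0.2)

    def test_validation_rows_cannot_leak_into_fold_statistics(self, rng):
        """Perturbing one held-out sample changes only its own prediction."""
        x, y = correlated_index_matrix(60, rng, n_cols=10)
        cv = CVConfig(5, seed=3)
        base = fit_predict_gpr(x, y, cv)
        x2 = x.copy()
        fold0_val = cv.folds(60)[0][1]
        victim = fold0_val[0]
        x2[victim] += 10.0
        shifted = fit_predict_gpr(x2, y, cv)
        # the rest of fold 0's held-out rows are predicted by a model fitted
        # without the victim, so their predictions must be bit-unchanged
        others = np.setdiff1d(fold0_val, [victim])
        np.testing.assert_allclose(shifted.predictions[others], base.predictions[others])
        assert abs(shifted.predictions[victim] - base.predictions[victim]) > 1e-6


class TestCNN:
    def test_learns_screened_index_structure(self, rng):
        x, y = correlated_index_matrix(200, rng, noise=0.0)
        report = fit_predict_cnn(x, y, CVConfig(10, seed=5), CNNArchitectureConfig.micro(40))
        assert report.metrics.r2 >= 0.8

    def test_architecture_invariants_enforced(self):
        with pytest.raises(ConfigurationError):
            CNNArchitectureConfig(kernel_sizes=(3, 3, 3, 3, 3))
        with pytest.raises(ConfigurationError):
            CNNArchitectureConfig(lstm_hidden=30, attention_heads=8)

    def test_deterministic_given_seeds(self, rng):
        x, y = correlated_index_matrix(45, rng, n_cols=30)
        arch = CNNArchitectureConfig.micro(10)
        a = fit_predict_cnn(x, y, CVConfig(3, seed=6), arch)
        b = fit_predict_cnn(x, y, CVConfig(3, seed=6), arch)
        np.testing.assert_array_equal(a.predictions, b.predictions)


class TestPermutationImportance:
    def test_signal_column_ranks_first_and_null_scores_near_zero(self, rng):
        n = 120
        x = rng.normal(size=(n, 8))
        y = 4.0 * x[:, 2] + 0.2 * rng.normal(size=n)  # only column 2 matters
        cv = CVConfig(5, seed=7)
        report = fit_predict_xgb(x, y, cv)
        result = permutation_importance(report, x, y, cv, n_repeats=5, seed=1)
        assert result.ranking[0] == 2
        null_cols = [j for j in range(8) if j != 2]
        for j in null_cols:
            assert abs(result.scores[j]) <= 2.0 * max(result.spread[j], 1e-6) + 0.05

    def test_identical_seed_identical_scores(self, rng):
        x, y = correlated_index_matrix(50, rng, n_cols=6)
        cv = CVConfig(5, seed=8)
        report = fit_predict_xgb(x, y, cv)
        a = permutation_importance(report, x, y, cv, n_repeats=3, seed=2)
        b = permutation_importance(report, x, y, cv, n_repeats=3, seed=2)
        np.testing.assert_array_equal(a.scores, b.scores)

    def test_unfitted_report_rejected(self, rng):
        x, y = correlated_index_matrix(30, rng, n_cols=4)
        cv = CVConfig(3, seed=1)
        report = fit_predict_xgb(x, y, cv)
        report.fold_predictors = []
        with pytest.raises(InputError):
            permutation_importance(report, x, y, cv)
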