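import json

import numpy as np
import pytest
from scipy import stats

from teaspec.errors import InputError
from teaspec.evaluation import (
    anova_tukey,
    compile_report,
    compute_metrics,
    load_report,
    pca_scores,
    save_report,
)
from teaspec.models import ModelReport


class TestMetrics:
    def test_perfect_prediction(self):
        m = compute_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (m.r2, m.rmse, m.re) == (1.0, 0.0, 0.0)

    def test_rmse_hand_fixture(self):
        assert compute_metrics([2.0, 4.0], [3.0, 3.0]).rmse == pytest.approx(1.0)

    def test_relative_error_hand_fixture(self):
        m = compute_metrics([10.0, 10.0], [11.0, 9.0])
        assert m.re == pytest.approx(10.0)

    def test_literal_relative_error_variant(self):
        m = compute_metrics([10.0, 10.0], [11.0, 9.0], literal_re=True)
        assert m.re == pytest.approx(1.0)

    def test_rmse_scales_linearly_under_common_rescaling(self, rng):
        o = rng.random(20) + 1.0
        p = o + rng.normal(size=20) * 0.1
        assert compute_metrics(3 * o, 3 * p).rmse == pytest.approx(
            3 * compute_metrics(o, p).rmse
        )

    def test_degenerate_inputs(self):
        assert np.isnan(compute_metrics([1.0, 1.0], [1.0, 2.0]).r2)  # constant observed
        with pytest.raises(InputError):
            compute_metrics([0.0, 1.0], [1.0, 2.0])  # zero observed


class TestAnovaTukey:
    def test_identical_groups_show_no_effect(self):
        comp = anova_tukey([1, 2, 3] * 3, ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        assert comp.f_statistic == pytest.approx(0.0)
        assert not any(p["significant"] for p in comp.tukey)
        assert len(set(comp.letters.values())) == 1

    def test_two_group_f_equals_squared_t(self, rng):
        a = rng.normal(size=12)
        b = rng.normal(loc=1.0, size=15)
        comp = anova_tukey(np.concatenate([a, b]), ["a"] * 12 + ["b"] * 15)
        t = stats.ttest_ind(a, b).statistic
        assert comp.f_statistic == pytest.approx(t**2)

    def test_hand_computed_three_group_fixture(self):
        # 3 groups x 5 values; F computed from explicit between/within sums
        data = {
            "g1": [5.0, 6.0, 7.0, 6.0, 6.0],
            "g2": [8.0, 9.0, 8.0, 10.0, 9.0],
            "g3": [4.0, 5.0, 4.0, 3.0, 4.0],
        }
        values = np.concatenate(list(data.values()))
        labels = sum(([k] * 5 for k in data), [])
        grand = values.mean()
        ssb = sum(5 * (np.mean(v) - grand) ** 2 for v in data.values())
        ssw = sum(((np.asarray(v) - np.mean(v)) ** 2).sum() for v in data.values())
        expected_f = (ssb / 2) / (ssw / 12)
        comp = anova_tukey(values, labels)
        assert comp.f_statistic == pytest.approx(expected_f)
        assert comp.p_value < 0.001
        assert comp.letters["g2"] == "a" and comp.letters["g1"] == "b"
        assert comp.letters["g3"] == "c"

    def test_group_with_single_value_rejected(self):
        with pytest.raises(InputError):
            anova_tukey([1.0, 2.0, 3.0], ["a", "a", "b"])


class TestPCA:
    def test_explained_variance_fractions_behave(self, small_table):
        res = pca_scores(small_table.reflectance[:20], n_components=5)
        evr = res.explained_variance_ratio
        assert evr.sum() <= 1.0 + 1e-12
        assert np.all(np.diff(evr) <= 1e-12)

    def test_matches_eigendecomposition_oracle(self, rng):
        x = rng.random((10, 20))
        res = pca_scores(x, n_components=5)
        xc = x - x.mean(axis=0)
        evals, evecs = np.linalg.eigh(np.cov(xc, rowvar=False, bias=False))
        order = np.argsort(evals)[::-1]
        for i in range(5):
            v = evecs[:, order[i]]
            if v[np.argmax(np.abs(v))] < 0:
                v = -v
            np.testing.assert_allclose(np.abs(res.components[i]), np.abs(v), atol=1e-8)
            np.testing.assert_allclose(res.scores[:, i], xc @ v, atol=1e-8)

    def test_duplicated_rows_leave_original_scores_stable(self, rng):
        x = rng.random((12, 15))
        base = pca_scores(x, n_components=3)
        dup = pca_scores(np.vstack([x, x]), n_components=3)
        # doubling every row preserves the component subspace exactly
        np.testing.assert_allclose(np.abs(dup.scores[:12]), np.abs(base.scores), atol=1e-8)

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(InputError):
            pca_scores(rng.random((2, 5)))


def _fake_report(model, y, preds):
    from teaspec.evaluation import compute_metrics

    return ModelReport(
        model, y, preds, np.zeros(len(y), int), compute_metrics(y, preds), [], seed=0
    )


class TestCompileReport:
    def _results(self, rng, perfect=True):
        from teaspec.grid import SEASONS, STATES

        means = {"spring": 21.5, "summer": 25.8, "autumn": 22.5}
        results = {}
        for season in SEASONS:
            y = means[season] + 0.5 * rng.normal(size=20)
            for state in STATES:
                preds = y if perfect else rng.permutation(y)
                for model in ("xgb", "cnn"):
                    results[(season, state, "polyphenols", model)] = _fake_report(
                        model, y, preds
                    )
        return results

    def test_cardinality_and_flags_for_perfect_predictions(self, rng):
        report = compile_report(self._results(rng))
        assert len(report["metrics"]) == 3 * 3 * 1 * 2
        flags = report["pattern_flags"]["polyphenols"]
        assert flags["season_effect_in_every_state"]
        assert flags["no_state_effect_in_any_season"]
        assert flags["summer_gt_autumn_gt_spring"]

    def test_round_trip_is_lossless(self, rng, tmp_path):
        report = compile_report(self._results(rng))
        path = tmp_path / "report.json"
        save_report(report, path)
        assert load_report(path) == json.loads(json.dumps(report))

    def test_inconsistent_observed_values_rejected(self, rng):
        results = self._results(rng)
        key = ("spring", "fresh", "polyphenols", "cnn")
        tampered = _fake_report("cnn", results[key].observed + 1.0,
                                results[key].predictions + 1.0)
        results[key] = tampered
        with pytest.raises(InputError, match="one run"):
            compile_report(results)
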