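import numpy as np
import pandas as pd
import pytest
from scipy import stats

from teaspec.errors import AssemblyError, InputError, ScreeningError
from teaspec.indices import (
    ALL_FORMULAS,
    DUAL_FORMULAS,
    FORMULAS_BY_NAME,
    IndexCandidate,
    SearchStrategy,
    build_model_inputs,
    enumerate_candidates,
    evaluate_index,
    screen_indices,
)
from teaspec.pool import build_feature_pool
from teaspec.wavelets import cwt_matrix, select_wavelet_features


def brute_force_screen(values: pd.DataFrame, target, formulas, top_k):
    """Plain enumeration + per-candidate Pearson ranking: the oracle."""
    y = np.asarray(target, float)
    out = {}
    for formula in formulas:
        entries = []
        for _, slots in enumerate_candidates(values.columns, [formula]):
            col = evaluate_index(formula, [values[s].to_numpy() for s in slots])
            if not np.isfinite(col).all() or np.ptp(col) == 0:
                continue
            r = stats.pearsonr(col, y).statistic
            entries.append((min(r * r, 1.0), slots))
        entries.sort(key=lambda e: (-round(e[0], 12), e[1]))
        out[formula.name] = [
            IndexCandidate(formula.name, s, float(r2)) for r2, s in entries[:top_k]
        ]
    return out


class TestEvaluate:
    def test_ndvi_antisymmetry_and_zero_on_equal_slots(self):
        assert evaluate_index(FORMULAS_BY_NAME["NDVI"], (0.7, 0.7)) == 0.0
        a, b = 0.8, 0.3
        assert evaluate_index(FORMULAS_BY_NAME["NDVI"], (a, b)) == pytest.approx(
            -evaluate_index(FORMULAS_BY_NAME["NDVI"], (b, a))
        )

    def test_rvi_is_a_plain_quotient(self):
        assert evaluate_index(FORMULAS_BY_NAME["RVI"], (0.6, 0.3)) == pytest.approx(2.0)

    def test_savi_hand_evaluation(self):
        assert evaluate_index(FORMULAS_BY_NAME["SAVI"], (0.8, 0.4)) == pytest.approx(
            (0.4 * 1.5) / 1.7
        )

    def test_triple_formulas_hand_evaluations(self):
        a, b, c = 0.6, 0.4, 0.1
        cases = {
            "MTCI": (a - b) / (b - c),
            "DCNI": ((a - b) / (b - c)) / (a - c + 0.03),
            "MNDI": (a - b) / ((a - b) - (b - c)),
            "MCARI2": ((a - b) - 0.2 * (a - c)) * (a / b),
            "MEVI": (a - b) / (a + 2.5 * b - 1.5 * c + 1.0),
        }
        for name, expected in cases.items():
            assert evaluate_index(FORMULAS_BY_NAME[name], (a, b, c)) == pytest.approx(expected)

    def test_near_zero_denominator_returns_non_finite(self):
        value = evaluate_index(FORMULAS_BY_NAME["RVI"], (0.5, 1e-14))
        assert not np.isfinite(value)

    def test_arity_mismatch_rejected(self):
        with pytest.raises(InputError):
            evaluate_index(FORMULAS_BY_NAME["NDVI"], (0.1, 0.2, 0.3))


class TestEnumeration:
    def test_unordered_pair_count(self):
        names = list("abcd")
        cands = list(enumerate_candidates(names, [FORMULAS_BY_NAME["NDVI"]]))
        assert len(cands) == 6

    def test_ordered_pair_count(self):
        names = list("abcd")
        cands = list(enumerate_candidates(names, [FORMULAS_BY_NAME["RVI"]]))
        assert len(cands) == 12

    def test_ordered_triple_count(self):
        names = list("abcde")
        cands = list(enumerate_candidates(names, [FORMULAS_BY_NAME["MTCI"]]))
        assert len(cands) == 5 * 4 * 3

    def test_strided_restriction_matches_full_enumeration_of_subpool(self):
        names = [f"f{i}" for i in range(10)]
        strided = list(
            enumerate_candidates(names, [FORMULAS_BY_NAME["NDVI"]], SearchStrategy.strided(2))
        )
        subpool = list(
            enumerate_candidates(names[::2], [FORMULAS_BY_NAME["NDVI"]])
        )
        assert [s for _, s in strided] == [s for _, s in subpool]

    def test_subsample_is_deterministic(self):
        names = [f"f{i}" for i in range(30)]
        s = SearchStrategy.subsample(10, seed=4)
        assert s.restrict(names) == s.restrict(names)
        assert len(s.restrict(names)) == 10


class TestScreening:
    def test_planted_linear_relation_ranks_first_with_r2_one(self, rng):
        n = 40
        f2 = rng.random(n)
        target = rng.normal(size=n)
        values = pd.DataFrame(
            {"f1": target + f2, "f2": f2, "f3": rng.random(n), "f4": rng.random(n)}
        )
        ranked = screen_indices(values, target, formulas=[FORMULAS_BY_NAME["DVI"]], top_k=3)
        best = ranked["DVI"][0]
        assert best.slots == ("f1", "f2")
        assert best.r2 == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force_oracle_on_small_pool(self, rng):
        n, p = 25, 12
        values = pd.DataFrame(
            rng.random((n, p)) + 0.05, columns=[f"x{i:02d}" for i in range(p)]
        )
        target = rng.normal(size=n)
        fast = screen_indices(values, target, top_k=10)
        slow = brute_force_screen(values, target, ALL_FORMULAS, top_k=10)
        assert set(fast) == set(slow)
        for name in fast:
            assert [c.slots for c in fast[name]] == [c.slots for c in slow[name]], name
            np.testing.assert_allclose(
                [c.r2 for c in fast[name]], [c.r2 for c in slow[name]], atol=1e-10
            )

    def test_screening_invariant_to_affine_target_rescaling(self, rng):
        values = pd.DataFrame(rng.random((30, 6)), columns=list("abcdef"))
        target = rng.normal(size=30)
        a = screen_indices(values, target, formulas=DUAL_FORMULAS, top_k=5)
        b = screen_indices(values, 3.0 * target - 7.0, formulas=DUAL_FORMULAS, top_k=5)
        for name in a:
            assert [c.slots for c in a[name]] == [c.slots for c in b[name]]

    def test_fifty_dual_candidates_from_five_formulations(self, rng):
        values = pd.DataFrame(
            rng.random((30, 20)) + 0.05, columns=[f"x{i:02d}" for i in range(20)]
        )
        ranked = screen_indices(values, rng.normal(size=30), formulas=DUAL_FORMULAS, top_k=10)
        assert sum(len(v) for v in ranked.values()) == 50

    def test_constant_target_rejected(self, rng):
        values = pd.DataFrame(rng.random((10, 4)), columns=list("abcd"))
        with pytest.raises(ScreeningError):
            screen_indices(values, np.ones(10), formulas=DUAL_FORMULAS)


class TestModelInputs:
    def _ranked(self, values, target, top_k=3):
        return screen_indices(values, target, top_k=top_k)

    def test_column_count_and_screening_r2_reproduction(self, rng):
        n, p = 30, 10
        values = pd.DataFrame(
            rng.random((n, p)) + 0.05, columns=[f"x{i:02d}" for i in range(p)]
        )
        target = rng.normal(size=n)
        ranked = self._ranked(values, target)
        matrix = build_model_inputs(ranked, values, expected_per_formula=3)
        assert matrix.values.shape == (n, 30)
        assert np.isfinite(matrix.values).all()
        for j, cand in enumerate(matrix.candidates):
            r = stats.pearsonr(matrix.values[:, j], target).statistic
            assert r * r == pytest.approx(cand.r2, abs=1e-9)

    def test_duplicate_candidates_rejected(self, rng):
        values = pd.DataFrame(rng.random((12, 4)) + 0.1, columns=list("abcd"))
        cand = IndexCandidate("DVI", ("a", "b"), 0.5)
        with pytest.raises(AssemblyError, match="duplicate"):
            build_model_inputs({"DVI": [cand, cand]}, values)

    def test_shortfall_is_named(self, rng):
        values = pd.DataFrame(rng.random((12, 4)) + 0.1, columns=list("abcd"))
        ranked = screen_indices(values, rng.normal(size=12),
                                formulas=[FORMULAS_BY_NAME["DVI"]], top_k=4)
        with pytest.raises(AssemblyError, match="DVI"):
            build_model_inputs(ranked, values, expected_per_formula=10)


def test_standard_pool_has_1960_uniquely_named_features(fresh_spring):
    refl = fresh_spring.reflectance
    coeffs = cwt_matrix(refl)
    _, wf = select_wavelet_features(coeffs, fresh_spring.chemistry("polyphenols"))
    pool = build_feature_pool(refl, fresh_spring.wavelengths, wf)
    assert pool.n_features == 1960
    assert pool.domain_counts() == {"R": 490, "HF": 980, "WF": 490}
    assert len(set(pool.feature_names)) == 1960
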