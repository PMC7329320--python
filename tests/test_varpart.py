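"""Hellinger transform, RDA adjusted R^2, partitioning, permutation test,
and correlation heat-map statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from stoichres import (correlation_heatmap_stats, hellinger,
                       permutation_test_fraction, rda_adjusted_r2, varpart2)
from stoichres.errors import (CollinearityError, DegenerateInputError,
                              InvalidArgumentError, InvalidInputError)
from stoichres.varpart import adjusted_r2


class TestHellinger:
    def test_single_nonzero_column(self):
        np.testing.assert_allclose(hellinger(np.array([[4.0, 0.0]])),
                                   [[1.0, 0.0]])

    def test_equal_split_row(self):
        np.testing.assert_allclose(hellinger(np.array([[1.0, 1.0]])),
                                   [[0.70710678, 0.70710678]], atol=1e-8)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(1, 6), st.integers(1, 6), st.integers(0, 2 ** 31 - 1))
    def test_rows_have_unit_sum_of_squares(self, n, m, seed):
        rng = np.random.default_rng(seed)
        out = hellinger(rng.uniform(0.01, 10.0, (n, m)))
        np.testing.assert_allclose((out ** 2).sum(axis=1), 1.0, atol=1e-12)

    def test_error_paths(self):
        with pytest.raises(InvalidInputError):
            hellinger(np.array([[1.0, -1.0]]))
        with pytest.raises(DegenerateInputError, match="row"):
            hellinger(np.array([[1.0, 1.0], [0.0, 0.0]]))


class TestRdaAdjustedR2:
    def test_exact_linear_map_gives_one(self, rng):
        X = rng.standard_normal((30, 3))
        Y = X @ rng.standard_normal((3, 5))
        r2, _ = rda_adjusted_r2(Y, X)
        assert r2 == pytest.approx(1.0, abs=1e-10)

    def test_orthogonal_response_gives_zero(self):
        n = 16
        X = np.column_stack([np.sin(2 * np.pi * np.arange(n) / n)])
        Y = np.column_stack([np.cos(2 * np.pi * np.arange(n) / n)])
        r2, _ = rda_adjusted_r2(Y, X)
        assert r2 == pytest.approx(0.0, abs=1e-9)

    def test_matches_column_wise_ols_oracle(self, rng):
        n = 40
        X = rng.standard_normal((n, 4))
        Y = X @ rng.standard_normal((4, 6)) + rng.standard_normal((n, 6))
        r2, adj = rda_adjusted_r2(Y, X)
        Yc = Y - Y.mean(0)
        X1 = np.column_stack([np.ones(n), X])
        explained = 0.0
        for j in range(Y.shape[1]):
            beta, *_ = np.linalg.lstsq(X1, Yc[:, j], rcond=None)
            fitted = X1 @ beta
            explained += ((fitted - fitted.mean()) ** 2).sum()
        oracle = explained / (Yc ** 2).sum()
        assert r2 == pytest.approx(oracle, abs=1e-10)
        assert adj == pytest.approx(adjusted_r2(oracle, n, 4), abs=1e-12)

    def test_adjusted_approaches_raw_at_large_n(self, rng):
        n = 100_000
        X = rng.standard_normal((n, 3))
        Y = X @ rng.standard_normal((3, 2)) + rng.standard_normal((n, 2))
        r2, adj = rda_adjusted_r2(Y, X)
        assert adj == pytest.approx(r2, abs=1e-4)

    def test_collinearity_names_dependent_column(self, rng):
        X = pd.DataFrame({"a": rng.standard_normal(20)})
        X["b"] = 2.0 * X["a"]
        Y = rng.standard_normal((20, 2))
        with pytest.raises(CollinearityError, match="b"):
            rda_adjusted_r2(Y, X)


class TestVarpart2:
    def test_identical_sets_have_zero_unique_fractions(self, rng):
        X = rng.standard_normal((40, 2))
        Y = X @ rng.standard_normal((2, 3)) + 0.3 * rng.standard_normal((40, 3))
        res = varpart2(Y, X, X.copy())
        assert res.frac_unique_M == pytest.approx(0.0, abs=1e-9)
        assert res.frac_unique_S == pytest.approx(0.0, abs=1e-9)
        assert res.frac_shared == pytest.approx(res.adj_r2_M, abs=1e-9)

    def test_pure_S_structure_leaves_no_unique_M(self, rng):
        n = 2000
        X_S = rng.standard_normal((n, 3))
        X_M = rng.standard_normal((n, 2))
        Y = X_S @ rng.standard_normal((3, 4)) + rng.standard_normal((n, 4))
        res = varpart2(Y, X_M, X_S)
        assert res.frac_unique_M == pytest.approx(0.0, abs=0.02)

    def test_fractions_sum_to_one_and_match_inclusion_exclusion(self, rng):
        def oracle_adj(Y, X):
            n, p = X.shape
            Yc = Y - Y.mean(0)
            X1 = np.column_stack([np.ones(n), X])
            sse = 0.0
            for j in range(Yc.shape[1]):
                beta, *_ = np.linalg.lstsq(X1, Yc[:, j], rcond=None)
                sse += ((Yc[:, j] - X1 @ beta) ** 2).sum()
            r2 = 1.0 - sse / (Yc ** 2).sum()
            return adjusted_r2(r2, n, p)

        for _ in range(20):
            n = 50
            X_M = rng.standard_normal((n, 2))
            X_S = rng.standard_normal((n, 3))
            Y = (X_S @ rng.standard_normal((3, 5))
                 + 0.5 * X_M @ rng.standard_normal((2, 5))
                 + rng.standard_normal((n, 5)))
            res = varpart2(Y, X_M, X_S)
            am = oracle_adj(Y, X_M)
            as_ = oracle_adj(Y, X_S)
            ams = oracle_adj(Y, np.column_stack([X_M, X_S]))
            assert res.frac_unique_M == pytest.approx(ams - as_, abs=1e-10)
            assert res.frac_unique_S == pytest.approx(ams - am, abs=1e-10)
            assert res.frac_shared == pytest.approx(am + as_ - ams, abs=1e-10)
            assert (res.frac_unique_M + res.frac_unique_S + res.frac_shared
                    + res.frac_residual) == pytest.approx(1.0, abs=1e-9)


class TestPermutationTestFraction:
    def test_identical_seed_identical_p(self, rng):
        Y = rng.standard_normal((30, 2))
        XM = rng.standard_normal((30, 2))
        XS = rng.standard_normal((30, 2))
        p1 = permutation_test_fraction(Y, XM, XS, "M", n_perm=99, seed=5)
        p2 = permutation_test_fraction(Y, XM, XS, "M", n_perm=99, seed=5)
        assert p1 == p2

    def test_strong_effect_saturates_null(self, rng):
        n = 54
        XM = rng.standard_normal((n, 2))
        XS = rng.standard_normal((n, 3))
        Y = XM @ rng.standard_normal((2, 4)) + 0.05 * rng.standard_normal((n, 4))
        p = permutation_test_fraction(Y, XM, XS, "M", n_perm=999, seed=0)
        assert p == pytest.approx(1.0 / 1000.0)

    def test_n_perm_floor(self, rng):
        Y = rng.standard_normal((20, 2))
        X = rng.standard_normal((20, 2))
        with pytest.raises(InvalidArgumentError):
            permutation_test_fraction(Y, X, X, "M", n_perm=50)


class TestCorrelationHeatmapStats:
    def test_perfect_correlation_gets_three_stars(self):
        x = pd.DataFrame({"mat": np.arange(10.0)})
        y = pd.DataFrame({"nifH": 2.0 * np.arange(10.0) + 1.0})
        out = correlation_heatmap_stats(x, y)
        assert out["r"].iloc[0] == pytest.approx(1.0, abs=1e-12)
        assert out["stars"].iloc[0] == "***"

    def test_orthogonal_pair_has_zero_r_and_blank_stars(self):
        n = 16
        t = 2 * np.pi * np.arange(n) / n
        out = correlation_heatmap_stats(pd.DataFrame({"mat": np.sin(t)}),
                                        pd.DataFrame({"nifH": np.cos(t)}))
        assert out["r"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert out["stars"].iloc[0] == ""

    def test_matches_formula_oracle(self, rng):
        x = pd.DataFrame({"v": rng.standard_normal(25)})
        y = pd.DataFrame({"g": rng.standard_normal(25)})
        out = correlation_heatmap_stats(x, y)
        xv, yv = x["v"], y["g"]
        r = (((xv - xv.mean()) * (yv - yv.mean())).sum()
             / np.sqrt(((xv - xv.mean()) ** 2).sum()
                       * ((yv - yv.mean()) ** 2).sum()))
        t = r * np.sqrt(23 / (1 - r ** 2))
        p = 2 * stats.t.sf(abs(t), 23)
        assert out["r"].iloc[0] == pytest.approx(r, abs=1e-10)
        assert out["p"].iloc[0] == pytest.approx(p, rel=1e-6)

    def test_constant_column_flagged_not_fatal(self):
        x = pd.DataFrame({"mat": np.ones(10)})
        y = pd.DataFrame({"nifH": np.arange(10.0)})
        out = correlation_heatmap_stats(x, y)
        assert out["undefined"].iloc[0]
        assert np.isnan(out["r"].iloc[0])
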