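"""OLS core, information criteria, exhaustive and genetic subset search."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from critdepth.model_selection import (
    SelectionConfig,
    SingularDesignError,
    aic,
    aicc,
    best_subset,
    exhaustive_best_subset,
    genetic_best_subset,
    ols_fit,
)


def naive_best_subset(X: pd.DataFrame, y, criterion="aicc", max_size=None):
    """Full-enumeration oracle using plain lstsq fits, independent of the
    Gram-matrix evaluation path."""
    n = len(y)
    max_size = max_size if max_size is not None else n - 4
    names = list(X.columns)
    best = (np.inf, ())
    for size in range(0, min(max_size, len(names)) + 1):
        for subset in combinations(range(len(names)), size):
            Z = np.column_stack([np.ones(n)] + [X.iloc[:, j] for j in subset])
            beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
            rss = float(np.sum((y - Z @ beta) ** 2))
            k = size + 2
            if rss <= 0:
                ll = np.inf
            else:
                ll = -0.5 * n * (np.log(2 * np.pi * rss / n) + 1)
            c = aicc(ll, n, k) if criterion == "aicc" else aic(ll, k)
            if c < best[0] - 1e-12:
                best = (c, subset)
    return best


class TestOlsFit:
    def test_perfect_fit(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 2)), columns=["a", "b"])
        y = 1 + 2 * X["a"] - 3 * X["b"]
        fit = ols_fit(X, y)
        assert fit.adj_r2 == pytest.approx(1.0)
        assert fit.rss == pytest.approx(0.0, abs=1e-18)
        assert fit.coefficients["a"] == pytest.approx(2.0)

    def test_intercept_only_r2_zero(self, rng):
        y = rng.normal(size=12)
        fit = ols_fit(pd.DataFrame(index=range(12)), y)
        assert fit.r2 == pytest.approx(0.0)
        assert fit.coefficients["intercept"] == pytest.approx(y.mean())

    def test_normal_equations_oracle(self):
        X = pd.DataFrame({"a": [1.0, 2, 3, 4, 5, 6], "b": [2.0, 1, 4, 3, 6, 5]})
        y = np.array([1.0, 3, 2, 5, 4, 6])
        Z = np.column_stack([np.ones(6), X])
        beta = np.linalg.solve(Z.T @ Z, Z.T @ y)
        fit = ols_fit(X, y)
        got = [fit.coefficients["intercept"], fit.coefficients["a"], fit.coefficients["b"]]
        assert np.allclose(got, beta, atol=1e-10)

    def test_rank_deficient_names_aliased_column(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=8)})
        X["b"] = 2 * X["a"]
        with pytest.raises(SingularDesignError, match="b"):
            ols_fit(X, rng.normal(size=8))

    def test_adj_r2_invariant_to_predictor_rescaling(self, rng):
        X = pd.DataFrame(rng.normal(size=(15, 3)), columns=list("abc"))
        y = rng.normal(size=15) + X["a"]
        f1 = ols_fit(X, y)
        X2 = X.copy()
        X2["b"] = 1000 * X2["b"] - 7
        assert ols_fit(X2, y).adj_r2 == pytest.approx(f1.adj_r2, abs=1e-10)


class TestAicc:
    def test_small_sample_correction_value(self):
        ll = -40.0
        assert aicc(ll, 27, 4) == pytest.approx(aic(ll, 4) + 2 * 4 * 5 / 22)
        assert 2 * 4 * 5 / 22 == pytest.approx(1.8181818181818181)

    def test_converges_to_aic(self):
        assert aicc(-40.0, 10**9, 4) == pytest.approx(aic(-40.0, 4), abs=1e-6)

    def test_boundary_inadmissible(self):
        assert aicc(-40.0, 6, 5) == np.inf  # n - k - 1 = 0

    @pytest.mark.parametrize("n,k", [(27, 3), (27, 10), (10, 5), (100, 2)])
    def test_never_below_aic(self, n, k):
        assert aicc(-12.3, n, k) >= aic(-12.3, k)


class TestExhaustiveSearch:
    def test_dominant_predictor_selected(self, rng):
        X = pd.DataFrame(rng.normal(size=(27, 3)), columns=["x1", "x2", "x3"])
        y = 5 * X["x1"] + 0.01 * rng.normal(size=27)
        fit = exhaustive_best_subset(X, y)
        assert fit.selected == ("x1",)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(5):
            X = pd.DataFrame(
                rng.normal(size=(27, 8)), columns=[f"x{i}" for i in range(8)]
            )
            y = X["x0"] - 0.7 * X["x3"] + rng.normal(size=27)
            fit = exhaustive_best_subset(X, y)
            crit, subset = naive_best_subset(X, y)
            assert tuple(X.columns[j] for j in subset) == fit.selected
            assert fit.criterion_value == pytest.approx(crit, rel=1e-10)

    def test_pure_noise_beats_nothing_enumerated(self, rng):
        X = pd.DataFrame(rng.normal(size=(27, 6)), columns=[f"x{i}" for i in range(6)])
        y = rng.normal(size=27)
        fit = exhaustive_best_subset(X, y)
        crit, _ = naive_best_subset(X, y)
        assert fit.criterion_value <= crit + 1e-9

    def test_aic_criterion_for_richness_style_models(self, rng):
        X = pd.DataFrame(rng.normal(size=(27, 5)), columns=[f"x{i}" for i in range(5)])
        y = X["x1"] + rng.normal(size=27)
        fit = exhaustive_best_subset(X, y, SelectionConfig(criterion="aic"))
        crit, subset = naive_best_subset(X, y, criterion="aic")
        assert tuple(X.columns[j] for j in subset) == fit.selected


class TestGeneticSearch:
    def test_seeded_determinism(self, rng):
        X = pd.DataFrame(rng.normal(size=(27, 12)), columns=[f"x{i}" for i in range(12)])
        y = X["x2"] + 0.5 * X["x7"] + rng.normal(size=27)
        cfg = SelectionConfig(seed=99)
        f1 = genetic_best_subset(X, y, cfg)
        f2 = genetic_best_subset(X, y, cfg)
        assert f1.selected == f2.selected

    def test_degenerate_population_contract(self, rng):
        X = pd.DataFrame(rng.normal(size=(27, 4)), columns=list("abcd"))
        y = rng.normal(size=27)
        cfg = SelectionConfig(population=1, generations=0, elitism=1, seed=3)
        fit = genetic_best_subset(X, y, cfg)  # best of the initial sample
        assert set(fit.selected) <= set("abcd")

    def test_matches_exhaustive_on_small_instances(self, rng):
        hits = 0
        for s in range(10):
            X = pd.DataFrame(
                rng.normal(size=(27, 10)), columns=[f"x{i}" for i in range(10)]
            )
            y = X["x1"] - X["x6"] + rng.normal(size=27)
            ex = exhaustive_best_subset(X, y)
            ga = genetic_best_subset(X, y, SelectionConfig(seed=s))
            hits += ga.criterion_value <= ex.criterion_value + 1e-9
        assert hits >= 9

    def test_never_better_than_exhaustive(self, rng):
        X = pd.DataFrame(rng.normal(size=(27, 9)), columns=[f"x{i}" for i in range(9)])
        y = rng.normal(size=27)
        ex = exhaustive_best_subset(X, y)
        ga = genetic_best_subset(X, y, SelectionConfig(seed=0))
        assert ga.criterion_value >= ex.criterion_value - 1e-9


class TestDispatchAndNesting:
    def test_auto_dispatch_small_uses_exhaustive(self, rng):
        X = pd.DataFrame(rng.normal(size=(27, 5)), columns=[f"x{i}" for i in range(5)])
        y = X["x0"] + rng.normal(size=27)
        fit = best_subset(X, y)
        assert fit.selected == exhaustive_best_subset(X, y).selected

    def test_rss_nesting_monotonicity(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 6)), columns=[f"x{i}" for i in range(6)])
        y = rng.normal(size=20)
        rss = [
            ols_fit(X.iloc[:, :k], y).rss if k else ols_fit(pd.DataFrame(index=range(20)), y).rss
            for k in range(7)
        ]
        assert all(b <= a + 1e-9 for a, b in zip(rss, rss[1:]))
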