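import math

import numpy as np
import pytest
from scipy import stats

from pathassoc.association import (
    ModelSpec,
    age_category,
    birth_year_ordinal,
    crude_or_2x2,
    fit_logistic,
    genotype_category_or,
    interaction_lrt,
    trend_p_matrix,
    trend_test,
)
from tests.conftest import make_dataset

# Published genotype counts for the top SERPINA5 SNP (rs6115):
# cases (AA, AG, GG) and controls (AA, AG, GG).
RS6115_CASES = (119, 148, 71)
RS6115_CONTROLS = (228, 161, 54)


def _expand(cases, controls):
    g = np.concatenate([np.repeat([0, 1, 2], cases), np.repeat([0, 1, 2], controls)])
    y = np.concatenate([np.ones(sum(cases)), np.zeros(sum(controls))])
    return g.astype(float), y


class TestFitLogistic:
    def test_balanced_independent_predictor_gives_or_one(self):
        x = np.array([0, 0, 1, 1] * 10, dtype=float)
        y = np.array([0, 1, 0, 1] * 10, dtype=float)
        X = np.column_stack([np.ones_like(x), x])
        fit = fit_logistic(y, X)
        assert fit.converged
        assert fit.params[1] == pytest.approx(0.0, abs=1e-8)

    def test_2x2_slope_matches_cross_product(self):
        # all-positive 2x2 table (a, b; c, d): slope = log(ad/bc)
        a, b, c, d = 30, 20, 10, 40
        x = np.concatenate([np.ones(a + c), np.zeros(b + d)])
        y = np.concatenate([np.ones(a), np.zeros(c), np.ones(b), np.zeros(d)])
        fit = fit_logistic(y, np.column_stack([np.ones_like(x), x]))
        assert fit.params[1] == pytest.approx(math.log(a * d / (b * c)), abs=1e-8)

    def test_beats_grid_search(self, rng):
        x = rng.normal(size=80)
        y = (rng.random(80) < 1 / (1 + np.exp(-(0.3 + 0.8 * x)))).astype(float)
        X = np.column_stack([np.ones_like(x), x])
        fit = fit_logistic(y, X)

        def llf(b0, b1):
            eta = b0 + b1 * x
            return float(np.sum(y * eta - np.log1p(np.exp(eta))))

        grid = np.linspace(-5, 5, 41)
        best = max(llf(b0, b1) for b0 in grid for b1 in grid)
        assert fit.llf >= best - 1e-9

    def test_separation_flagged_not_reported(self):
        x = np.array([0, 0, 0, 1, 1, 1], dtype=float)
        y = np.array([0, 0, 0, 1, 1, 1], dtype=float)
        fit = fit_logistic(y, np.column_stack([np.ones_like(x), x]))
        assert not fit.converged

    def test_aliased_column_dropped_rightmost(self):
        x = np.array([0, 1, 0, 1, 0, 1, 1, 0], dtype=float)
        y = np.array([0, 1, 1, 0, 0, 1, 0, 1], dtype=float)
        X = np.column_stack([np.ones_like(x), x, x])  # duplicate column
        fit = fit_logistic(y, X, column_names=["intercept", "x", "x_dup"])
        assert fit.dropped_columns == ["x_dup"]


class TestCovariateCoding:
    def test_age_boundaries_left_closed(self):
        assert list(age_category(np.array([34, 35, 44, 45, 54, 55]))) == [0, 1, 1, 2, 2, 3]

    def test_birth_year_ordinal(self):
        assert list(birth_year_ordinal(np.array([1939, 1940, 1949, 1950, 1980]))) == [0, 1, 1, 2, 2]


class TestTrendTest:
    def test_crude_fit_on_published_counts_matches_grid_oracle(self):
        # per-allele model on the rs6115 table; validated against a direct
        # likelihood grid, not against the published covariate-adjusted values
        g, y = _expand(RS6115_CASES, RS6115_CONTROLS)
        ds = make_dataset(g[:, None], y)
        or_, ci, p, fit = trend_test(g, ds, ModelSpec(adjusted=False))
        assert fit.converged and p < 1e-4
        b_grid = np.linspace(0.3, 0.7, 2001)

        def llf(b1):
            # profile the intercept coarsely
            b0s = np.linspace(-1.2, 0.2, 141)
            eta = b0s[:, None] + b1 * g[None, :]
            return np.max(np.sum(y[None, :] * eta - np.log1p(np.exp(eta)), axis=1))

        best_b1 = b_grid[int(np.argmax([llf(b) for b in b_grid]))]
        assert math.log(or_) == pytest.approx(best_b1, abs=5e-3)

    def test_zero_variance_dosage_flagged(self, balanced_dataset):
        g = np.zeros(balanced_dataset.n_subjects)
        or_, ci, p, fit = trend_test(g, balanced_dataset)
        assert math.isnan(p)

    def test_wald_and_lrt_agree_at_moderate_signal(self, rng):
        n = 400
        g = rng.binomial(2, 0.3, n).astype(float)
        y = (rng.random(n) < 1 / (1 + np.exp(-(-0.2 + 0.4 * g)))).astype(int)
        ds = make_dataset(g[:, None], y)
        *_, p_wald, _ = trend_test(g, ds, ModelSpec(adjusted=False, trend_statistic="wald"))
        *_, p_lrt, _ = trend_test(g, ds, ModelSpec(adjusted=False, trend_statistic="lrt"))
        assert math.log10(p_wald) == pytest.approx(math.log10(p_lrt), abs=0.3)

    def test_adjusted_close_to_crude_without_confounding(self, rng):
        # covariates independent of genotype: adjustment leaves the OR alone
        n = 600
        g = rng.binomial(2, 0.35, n).astype(float)
        y = (rng.random(n) < 1 / (1 + np.exp(-(-0.3 + math.log(1.6) * g)))).astype(int)
        ds = make_dataset(g[:, None], y,
                          sex=np.where(rng.random(n) < 0.1, "M", "F"),
                          birth_year=rng.integers(1930, 1980, n),
                          age=rng.integers(20, 70, n))
        or_adj, *_ = trend_test(g, ds, ModelSpec(adjusted=True))
        or_crude, *_ = trend_test(g, ds, ModelSpec(adjusted=False))
        assert or_adj == pytest.approx(or_crude, rel=0.05)


class TestGenotypeCategoryOr:
    def test_crude_ors_match_cross_products_on_published_counts(self):
        g, y = _expand(RS6115_CASES, RS6115_CONTROLS)
        ds = make_dataset(g[:, None], y)
        or_het, ci_het, or_hom, ci_hom, fit = genotype_category_or(g, ds, ModelSpec(adjusted=False))
        assert or_het == pytest.approx((148 * 228) / (161 * 119), abs=1e-6)
        assert or_hom == pytest.approx((71 * 228) / (54 * 119), abs=1e-6)
        assert ci_het[0] < or_het < ci_het[1]

    def test_balanced_fixture_gives_unit_ors(self):
        counts = (40, 40, 40)
        g, y = _expand(counts, counts)
        ds = make_dataset(g[:, None], y)
        or_het, _, or_hom, _, _ = genotype_category_or(g, ds, ModelSpec(adjusted=False))
        assert or_het == pytest.approx(1.0, abs=1e-8)
        assert or_hom == pytest.approx(1.0, abs=1e-8)

    def test_ci_width_halves_when_n_quadruples(self):
        g, y = _expand(RS6115_CASES, RS6115_CONTROLS)
        ds1 = make_dataset(g[:, None], y)
        g4, y4 = np.tile(g, 4), np.tile(y, 4)
        ds4 = make_dataset(g4[:, None], y4)
        _, ci1, *_ = genotype_category_or(g, ds1, ModelSpec(adjusted=False))
        _, ci4, *_ = genotype_category_or(g4, ds4, ModelSpec(adjusted=False))
        w1 = math.log(ci1[1]) - math.log(ci1[0])
        w4 = math.log(ci4[1]) - math.log(ci4[0])
        assert w4 == pytest.approx(w1 / 2, rel=0.10)


class TestInteractionLrt:
    def test_zero_variance_modifier_gives_p_one(self, rng):
        n = 200
        g = rng.binomial(2, 0.3, n).astype(float)
        y = np.tile([0, 1], n // 2)
        ds = make_dataset(g[:, None], y)
        p = interaction_lrt(g, np.zeros(n), ds, ModelSpec(adjusted=False))
        assert p == pytest.approx(1.0)

    def test_null_interaction_p_uniform(self, rng):
        n, reps = 300, 120
        ps = []
        for _ in range(reps):
            g = rng.binomial(2, 0.3, n).astype(float)
            mod = rng.binomial(1, 0.5, n).astype(float)
            y = (rng.random(n) < 1 / (1 + np.exp(-(-0.2 + 0.3 * g + 0.3 * mod)))).astype(int)
            ds = make_dataset(g[:, None], y)
            ps.append(interaction_lrt(g, mod, ds, ModelSpec(adjusted=False)))
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_power_against_planted_interaction(self, rng):
        n, reps = 2000, 60
        hits = 0
        for _ in range(reps):
            g = rng.binomial(2, 0.3, n).astype(float)
            mod = rng.binomial(1, 0.5, n).astype(float)
            eta = -0.5 + 0.2 * g + 0.2 * mod + 0.7 * g * mod
            y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
            ds = make_dataset(g[:, None], y)
            if interaction_lrt(g, mod, ds, ModelSpec(adjusted=False)) < 0.05:
                hits += 1
        assert hits / reps > 0.8


class TestCrudeOr2x2:
    def test_published_thyroiditis_table(self):
        # 48/277 exposed cases, 9/432 exposed controls -> crude OR 8.32
        or_, ci, corrected = crude_or_2x2(48, 277, 9, 432)
        assert or_ == pytest.approx(8.3177, abs=1e-3)
        assert not corrected and ci[0] < or_ < ci[1]

    def test_unit_table(self):
        or_, _, _ = crude_or_2x2(10, 10, 10, 10)
        assert or_ == pytest.approx(1.0)

    def test_reciprocity(self, rng):
        for _ in range(20):
            a, b, c, d = rng.integers(1, 50, 4)
            assert crude_or_2x2(a, b, c, d)[0] * crude_or_2x2(b, a, d, c)[0] == pytest.approx(1.0)

    def test_zero_cell_continuity_corrected(self):
        or_, _, corrected = crude_or_2x2(5, 0, 3, 10)
        assert corrected and np.isfinite(or_)


class TestVectorisedTrendMatrix:
    def test_matches_per_snp_statsmodels_fits(self, rng):
        """The vectorised Newton fitter and the statsmodels route are
        independent implementations of the same crude trend test."""
        n, k = 150, 6
        G = rng.binomial(2, 0.3, size=(n, k)).astype(float)
        G[rng.random((n, k)) < 0.05] = np.nan
        Y = np.vstack([np.tile([0, 1], n // 2), rng.permutation(np.tile([0, 1], n // 2))]).astype(float)
        P = trend_p_matrix(Y, G)
        for r in range(2):
            for j in range(k):
                ok = ~np.isnan(G[:, j])
                fit = fit_logistic(Y[r, ok], np.column_stack([np.ones(ok.sum()), G[ok, j]]))
                z2 = fit.params[1] ** 2 / fit.cov_params[1, 1]
                assert P[r, j] == pytest.approx(float(stats.chi2.sf(z2, 1)), abs=1e-6)

    def test_monomorphic_column_reported_uninformative(self, rng):
        n = 60
        G = np.column_stack([np.zeros(n), rng.binomial(2, 0.4, n)]).astype(float)
        Y = np.tile([0, 1], n // 2)[None, :].astype(float)
        P = trend_p_matrix(Y, G)
        assert P[0, 0] == 1.0 and P[0, 1] < 1.0
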