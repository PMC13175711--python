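from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from reefsync import (
    DataValidationError,
    SiteYearMatrix,
    bootstrap_rm_anova,
    classify_si,
    covariance_sign_consistency,
    posthoc_year_differences,
    si_null_distribution,
    synchrony_index,
    synchrony_with_null,
    two_tailed_binomial_p,
)
from reefsync.resampling import permute_within_taxa
from reefsync.synchrony import PairCovariance


def _matrix(values) -> SiteYearMatrix:
    values = np.asarray(values, dtype=float)
    return SiteYearMatrix(
        years=tuple(range(values.shape[0])),
        taxa=tuple(f"t{i}" for i in range(values.shape[1])),
        values=values,
    )


class TestSiNullDistribution:
    def test_single_taxon_null_is_all_ones(self):
        m = _matrix([[1.0], [4.0], [2.0]])
        null = si_null_distribution(m, n_reps=50, seed=0)
        # permuting a single population cannot change its SI (to float rounding)
        np.testing.assert_allclose(null, np.ones(50), rtol=1e-12)

    def test_permutation_preserves_each_taxon_multiset(self):
        rng = np.random.default_rng(3)
        values = rng.lognormal(1, 0.5, (6, 4))
        for _ in range(20):
            perm = permute_within_taxa(values, rng)
            for k in range(values.shape[1]):
                np.testing.assert_array_equal(
                    np.sort(perm[:, k]), np.sort(values[:, k])
                )

    def test_two_by_three_support_subset_of_enumeration(self):
        """Sampled null support is inside the brute-force enumeration of all
        36 joint permutations of a 2-taxon x 3-year matrix."""
        vals = np.array([[1.0, 5.0], [2.0, 9.0], [4.0, 6.0]])
        enumerated = set()
        for pa in permutations(range(3)):
            for pb in permutations(range(3)):
                m = _matrix(np.column_stack([vals[list(pa), 0], vals[list(pb), 1]]))
                enumerated.add(round(synchrony_index(m), 10))
        null = si_null_distribution(_matrix(vals), n_reps=500, seed=7)
        assert {round(x, 10) for x in null} <= enumerated

    def test_reproducible_under_fixed_seed(self):
        m = _matrix(np.random.default_rng(1).lognormal(1, 0.4, (5, 6)))
        a = si_null_distribution(m, n_reps=200, seed=123)
        b = si_null_distribution(m, n_reps=200, seed=123)
        np.testing.assert_array_equal(a, b)

    def test_degenerate_matrix_propagates_error(self):
        from reefsync import DegenerateCommunityError

        with pytest.raises(DegenerateCommunityError):
            si_null_distribution(_matrix([[1.0], [1.0], [1.0]]), n_reps=10, seed=0)


class TestClassifySi:
    def test_above_upper_bound_is_positive_covariation(self):
        null = np.linspace(0.01, 0.22, 1000)
        cls, low, high = classify_si(0.41, null)
        assert cls == "positive_covariation"
        assert low < high

    def test_inside_bounds_is_not_significant(self):
        null = np.linspace(0.01, 0.19, 1000)
        cls, _, _ = classify_si(0.18, null)
        assert cls == "not_significant"

    def test_below_lower_bound_is_negative_covariation(self):
        null = np.linspace(0.10, 0.30, 1000)
        cls, _, _ = classify_si(0.01, null)
        assert cls == "negative_covariation"

    def test_exact_tie_with_bound_is_not_significant(self):
        null = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        _, low, high = classify_si(0.3, null)
        assert classify_si(low, null)[0] == "not_significant"
        assert classify_si(high, null)[0] == "not_significant"

    def test_bounds_are_type7_quantiles(self):
        rng = np.random.default_rng(0)
        null = rng.random(501)
        _, low, high = classify_si(0.5, null, level=0.95)
        assert low == pytest.approx(np.quantile(null, 0.025))
        assert high == pytest.approx(np.quantile(null, 0.975))

    def test_synchrony_with_null_assembles_result(self):
        m = _matrix(np.random.default_rng(5).lognormal(1, 0.4, (5, 4)))
        res = synchrony_with_null(m, site="s1", phase="p1", n_reps=200, seed=9)
        assert res.null_quantile_low <= res.null_quantile_high
        assert res.n_reps == 200
        if res.observed_si > res.null_quantile_high:
            assert res.classification == "positive_covariation"


class TestBootstrapRmAnova:
    def test_df_for_15_sites_5_years(self):
        X = np.random.default_rng(0).normal(20, 3, (15, 5))
        res = bootstrap_rm_anova(X, n_reps=100, seed=0)
        assert (res.df_between, res.df_error) == (4, 56)

    def test_observed_f_matches_statsmodels_rm_anova(self):
        """Independent oracle: statsmodels AnovaRM on the same balanced design."""
        from statsmodels.stats.anova import AnovaRM

        rng = np.random.default_rng(8)
        X = rng.normal(15, 4, (10, 4))
        res = bootstrap_rm_anova(X, n_reps=50, seed=0)
        long = pd.DataFrame(
            {
                "site": np.repeat(np.arange(10), 4),
                "year": np.tile(np.arange(4), 10),
                "y": X.ravel(),
            }
        )
        f_sm = AnovaRM(long, "y", "site", within=["year"]).fit().anova_table["F Value"].iloc[0]
        assert res.f_observed == pytest.approx(float(f_sm), rel=1e-9)

    def test_constant_years_within_sites_give_p_1(self):
        X = np.tile(np.array([[3.0], [5.0], [9.0]]), (1, 4))
        res = bootstrap_rm_anova(X, n_reps=100, seed=0)
        assert res.f_observed == 0.0
        assert res.p_boot == 1.0

    def test_missing_cell_is_hard_error(self):
        X = np.ones((4, 3))
        X[1, 2] = np.nan
        with pytest.raises(DataValidationError, match="balanced"):
            bootstrap_rm_anova(X, n_reps=10, seed=0)

    def test_strong_year_effect_reaches_resampling_floor(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (12, 4)) + np.array([0.0, 0.0, 8.0, 0.0])
        res = bootstrap_rm_anova(X, n_reps=500, seed=3)
        assert res.p_boot == pytest.approx(1 / 501)

    def test_global_shuffle_mode_runs_and_is_seeded(self):
        X = np.random.default_rng(4).normal(20, 3, (6, 4))
        a = bootstrap_rm_anova(X, n_reps=200, seed=5, shuffle="global")
        b = bootstrap_rm_anova(X, n_reps=200, seed=5, shuffle="global")
        assert a.p_boot == b.p_boot

    def test_pvalues_uniform_under_exchangeable_null(self):
        """Kolmogorov-Smirnov check of p-value uniformity (alpha = 0.01)."""
        rng = np.random.default_rng(77)
        pvals = [
            bootstrap_rm_anova(rng.normal(10, 2, (8, 4)), n_reps=200, seed=rng).p_boot
            for _ in range(500)
        ]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestPosthocYearDifferences:
    def test_five_years_give_ten_pairs(self):
        X = np.random.default_rng(0).normal(20, 3, (6, 5))
        out = posthoc_year_differences(X, [1, 2, 3, 4, 5], n_reps=100, seed=0)
        assert len(out) == 10

    def test_identical_year_columns_give_zero_difference_and_p_near_1(self):
        col = np.random.default_rng(1).normal(20, 3, 8)
        X = np.column_stack([col, col])
        ((_, (diff, p)),) = posthoc_year_differences(X, [1, 2], n_reps=500, seed=2).items()
        assert diff == 0.0
        assert p > 0.9

    def test_large_injected_shift_hits_resampling_floor(self):
        rng = np.random.default_rng(3)
        X = np.column_stack([rng.normal(10, 1, 10), rng.normal(10, 1, 10) + 5 * 1.0 * 5])
        out = posthoc_year_differences(X, [1, 2], n_reps=400, seed=4)
        _, p = out[(1, 2)]
        assert p == pytest.approx(1 / 401)


class TestBinomialConsistency:
    @pytest.mark.parametrize(
        "k,n,expected",
        [
            (0, 1, 1.0),
            (15, 15, 2.0 ** -14),
            (12, 15, 1152 / 32768),
            (8, 15, 1.0),
        ],
    )
    def test_closed_forms(self, k, n, expected):
        assert two_tailed_binomial_p(k, n) == pytest.approx(expected, rel=1e-9)

    @pytest.mark.parametrize("n", [1, 5, 15, 30])
    def test_symmetry_and_scipy_cross_check(self, n):
        for k in range(n + 1):
            p = two_tailed_binomial_p(k, n)
            assert p == pytest.approx(two_tailed_binomial_p(n - k, n), rel=1e-12)
            assert p == pytest.approx(
                stats.binomtest(k, n, 0.5).pvalue, rel=1e-9
            )
            assert 0 < p <= 1

    def test_exhaustive_enumeration_oracle(self):
        """p equals the sum over outcomes no likelier than the observed one."""
        n = 15
        for k in range(n + 1):
            pk = stats.binom.pmf(k, n, 0.5)
            brute = sum(
                stats.binom.pmf(j, n, 0.5)
                for j in range(n + 1)
                if stats.binom.pmf(j, n, 0.5) <= pk + 1e-15
            )
            assert two_tailed_binomial_p(k, n) == pytest.approx(min(1.0, brute), rel=1e-9)

    def _records(self, signs_by_site):
        return {
            f"site{i}": [PairCovariance("a", "b", {"+" : 1.0, "-": -1.0, "0": 0.0, "undefined": 0.0}[s],
                                        float("nan") if s == "undefined" else 0.5, s)]
            for i, s in enumerate(signs_by_site)
        }

    def test_unanimous_15_sites_significant(self):
        out = covariance_sign_consistency(self._records("+" * 15), phase="p1")
        (rec,) = out
        assert rec.n_sites_present == 15
        assert rec.n_positive == 15
        assert rec.p_binomial == pytest.approx(2.0 ** -14, rel=1e-9)
        assert rec.significant

    def test_mixed_signs_not_significant(self):
        out = covariance_sign_consistency(self._records("+" * 8 + "-" * 7))
        (rec,) = out
        assert rec.p_binomial == 1.0
        assert not rec.significant

    def test_undefined_sites_do_not_count(self):
        out = covariance_sign_consistency(
            self._records(["+"] * 5 + ["undefined"] * 3)
        )
        (rec,) = out
        assert rec.n_sites_present == 5

    def test_zero_covariance_counts_present_but_neither_sign(self):
        out = covariance_sign_consistency(self._records("+" * 4 + "0"))
        (rec,) = out
        assert rec.n_sites_present == 5
        assert rec.n_positive == 4
        assert rec.n_negative == 0

    def test_all_undefined_pair_omitted_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="reefsync.resampling"):
            out = covariance_sign_consistency(self._records(["undefined"] * 3))
        assert out == []
        assert any("omitted" in r.message for r in caplog.records)

    def test_holm_adjustment_is_more_conservative(self):
        recs = {}
        for i in range(12):
            recs[f"s{i}"] = [
                PairCovariance("a", "b", 1.0, 0.5, "+"),
                PairCovariance("a", "c", 1.0, 0.5, "+" if i < 9 else "-"),
            ]
        raw = covariance_sign_consistency(recs, holm=False)
        adj = covariance_sign_consistency(recs, holm=True)
        raw_p = {(r.taxon_i, r.taxon_j): r.p_binomial for r in raw}
        adj_p = {(r.taxon_i, r.taxon_j): r.p_binomial for r in adj}
        for key in raw_p:
            assert adj_p[key] >= raw_p[key] - 1e-12
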