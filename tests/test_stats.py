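"""Permutation tests, split-plot ANOVA, chi-square and BH-FDR."""

import numpy as np
import pytest
from scipy import stats as sps

from netsig import stats
from netsig.errors import ParameterError
from oracles import brute_permutation_p, brute_split_plot_ss


class TestPermutationTest:
    def test_identical_samples_p_one(self):
        x = [1.0, 2.0, 3.0]
        res = stats.permutation_test(x, x, seed=0)
        assert res.observed == 0.0
        assert res.p == 1.0

    def test_exhaustive_oracle_small_samples(self, rng):
        for _ in range(10):
            x = rng.normal(0, 1, 4)
            y = rng.normal(0.5, 1, 5)
            res = stats.permutation_test(x, y, seed=1)
            assert res.exact  # 126 splits < default n_perm
            assert res.p == pytest.approx(brute_permutation_p(x, y), abs=1e-12)

    def test_p_floor_never_zero(self):
        res = stats.permutation_test([1.0, 2.0], [10.0, 11.0], seed=0)
        assert res.p >= 1.0 / res.n_perm

    def test_constant_pooled_sample_warns(self):
        with pytest.warns(UserWarning):
            res = stats.permutation_test([2.0, 2.0], [2.0, 2.0, 2.0])
        assert res.p == 1.0

    def test_type_one_error_quick(self):
        # a fast version of the calibration; the full 200-run version
        # lives in the acceptance suite
        rej = 0
        runs = 60
        rng = np.random.default_rng(7)
        for r in range(runs):
            x = rng.normal(0, 1, 30)
            y = rng.normal(0, 1, 30)
            p = stats.permutation_test(x, y, n_perm=500, seed=r).p
            rej += p <= 0.05
        assert 0.0 <= rej / runs <= 0.13

    def test_sample_size_precondition(self):
        with pytest.raises(ParameterError):
            stats.permutation_test([1.0], [2.0, 3.0])


class TestModalP:
    def test_deterministic_closure(self):
        assert stats.modal_p(lambda s: 0.04, n_repeats=10, seed=0) == 0.04

    def test_exact_test_mode_equals_exact_p(self, rng):
        x = rng.normal(0, 1, 4)
        y = rng.normal(1, 1, 4)
        exact = stats.permutation_test(x, y, seed=0).p
        modal = stats.modal_p(
            lambda s: stats.permutation_test(x, y, seed=s).p,
            n_repeats=20, seed=1)
        assert modal == pytest.approx(round(exact, 3), abs=1e-12)

    def test_stochastic_mode_near_exhaustive_truth(self, rng):
        # 8+8 samples: 12870 label splits, so a 10000-draw Monte-Carlo
        # test is genuinely stochastic while the exhaustive p is known
        x = rng.normal(0, 1, 8)
        y = rng.normal(1.0, 1, 8)
        exact = brute_permutation_p(list(x), list(y))
        modal = stats.modal_p(
            lambda s: stats.permutation_test(x, y, n_perm=10_000, seed=s).p,
            n_repeats=100, seed=2)
        assert abs(modal - exact) < 5e-3


class TestChi2:
    def test_balanced_table_null(self):
        s, df, p = stats.chi2_contingency([[10, 10], [10, 10]])
        assert s == 0.0 and df == 1 and p == 1.0

    def test_structural_etiology_contrast_significant(self):
        # 26/60 vs 10/60 with structural etiology: a clear association
        s, df, p = stats.chi2_contingency([[26, 34], [10, 50]])
        assert s > 0 and p < 0.05

    def test_textbook_formula_oracle(self, rng):
        table = rng.integers(5, 40, size=(2, 2)).astype(float)
        s, df, p = stats.chi2_contingency(table)
        total = table.sum()
        expect = np.outer(table.sum(1), table.sum(0)) / total
        s_ref = ((table - expect) ** 2 / expect).sum()
        assert s == pytest.approx(s_ref, rel=1e-12)
        assert p == pytest.approx(sps.chi2.sf(s_ref, 1), rel=1e-12)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ParameterError):
            stats.chi2_contingency([[0, 0], [5, 5]])


class TestMixedAnova:
    def _toy(self, rng, n_per=6, k=4, shift=0.0):
        a = rng.normal(0, 1, (n_per, k)) + np.linspace(0, 1, k)
        b = rng.normal(shift, 1, (n_per, k)) + np.linspace(0, 1, k)
        data = np.vstack([a, b])
        groups = np.array([0] * n_per + [1] * n_per)
        return data, groups

    def test_identical_groups_zero_f(self, rng):
        a = rng.normal(0, 1, (5, 4))
        data = np.vstack([a, a])
        groups = np.array([0] * 5 + [1] * 5)
        res = stats.mixed_anova(data, groups)
        assert res.effects["group"].f == pytest.approx(0.0, abs=1e-20)
        assert res.effects["interaction"].f == pytest.approx(0.0, abs=1e-20)

    def test_sums_of_squares_match_brute_force(self, rng):
        data, groups = self._toy(rng, shift=0.7)
        res = stats.mixed_anova(data, groups)
        ref = brute_split_plot_ss(data, groups)
        assert res.effects["group"].ss == pytest.approx(ref["group"], rel=1e-10)
        assert res.effects["band"].ss == pytest.approx(ref["band"], rel=1e-10)
        assert res.effects["interaction"].ss \
            == pytest.approx(ref["interaction"], rel=1e-10)
        assert res.ss_residual_between \
            == pytest.approx(ref["err_between"], rel=1e-10)
        assert res.ss_residual_within \
            == pytest.approx(ref["err_within"], rel=1e-10)
        # full decomposition closes
        total = (res.effects["group"].ss + res.ss_residual_between
                 + res.effects["band"].ss + res.effects["interaction"].ss
                 + res.ss_residual_within)
        assert total == pytest.approx(ref["total"], rel=1e-9)

    def test_unbalanced_groups_supported(self, rng):
        data = rng.normal(0, 1, (11, 4))
        groups = np.array([0] * 4 + [1] * 7)
        res = stats.mixed_anova(data, groups)
        ref = brute_split_plot_ss(data, groups)
        assert res.effects["group"].ss == pytest.approx(ref["group"], rel=1e-10)

    def test_compound_symmetry_epsilon_near_one(self, rng):
        # exchangeable covariance is spherical: epsilon ~ 1 at large n
        n, k = 200, 4
        shared = rng.normal(0, 1, (n, 1))
        data = shared + rng.normal(0, 1, (n, k))
        groups = (np.arange(n) < n // 2).astype(int)
        res = stats.mixed_anova(data, groups)
        assert res.gg_epsilon > 0.95
        assert res.mauchly_p > 0.01

    def test_cross_check_against_pingouin(self, rng):
        import pandas as pd
        import pingouin as pg

        data, groups = self._toy(rng, n_per=8, shift=0.5)
        res = stats.mixed_anova(data, groups)
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(16), 4),
            "band": np.tile(np.arange(4), 16),
            "group": np.repeat(groups, 4),
            "y": data.ravel(),
        })
        ref = pg.mixed_anova(long, dv="y", within="band", between="group",
                             subject="subject", correction=True)
        f_group = float(ref.loc[ref["Source"] == "group", "F"].iloc[0])
        f_band = float(ref.loc[ref["Source"] == "band", "F"].iloc[0])
        f_int = float(ref.loc[ref["Source"] == "Interaction", "F"].iloc[0])
        assert res.effects["group"].f == pytest.approx(f_group, rel=1e-8)
        assert res.effects["band"].f == pytest.approx(f_band, rel=1e-8)
        assert res.effects["interaction"].f == pytest.approx(f_int, rel=1e-8)
        # epsilon conventions differ slightly: this package pools the
        # within-group covariance (group cell means removed), pingouin
        # uses the total covariance; values agree closely but not exactly
        eps_ref = float(ref.loc[ref["Source"] == "band", "eps"].iloc[0])
        assert res.gg_epsilon == pytest.approx(eps_ref, abs=0.05)

    def test_tiny_group_rejected(self, rng):
        data = rng.normal(0, 1, (4, 4))
        with pytest.raises(ParameterError):
            stats.mixed_anova(data, np.array([0, 0, 0, 1]))


class TestTwowayAnova:
    def test_matches_statsmodels_type2(self, rng):
        import pandas as pd
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        n = 50
        fa = rng.integers(0, 2, n)
        fb = rng.integers(0, 2, n)
        y = rng.normal(0, 1, n) + 0.8 * fa + 0.4 * fa * fb
        res = stats.twoway_anova(y, fa, fb)
        df = pd.DataFrame({"y": y, "a": fa, "b": fb})
        ref = sm.stats.anova_lm(ols("y ~ C(a) * C(b)", df).fit(), typ=2)
        assert res["a"]["F"] == pytest.approx(ref.loc["C(a)", "F"], rel=1e-8)
        assert res["b"]["F"] == pytest.approx(ref.loc["C(b)", "F"], rel=1e-8)
        assert res["interaction"]["F"] \
            == pytest.approx(ref.loc["C(a):C(b)", "F"], rel=1e-8)

    def test_null_factors_not_significant(self, rng):
        n = 200
        y = rng.normal(0, 1, n)
        res = stats.twoway_anova(y, rng.integers(0, 2, n),
                                 rng.integers(0, 2, n))
        assert res["a"]["p"] > 0.001  # no systematic effect

    def test_single_level_factor_rejected(self, rng):
        with pytest.raises(ParameterError):
            stats.twoway_anova(rng.normal(0, 1, 10), np.zeros(10),
                               rng.integers(0, 2, 10))


class TestBhFdr:
    def test_step_up_all_rejected(self):
        res = stats.bh_fdr([0.01, 0.02, 0.03, 0.04], q=0.05)
        assert res.rejected.all()

    def test_single_p_adjusted_equals_raw(self):
        res = stats.bh_fdr([0.031])
        assert res.adjusted[0] == pytest.approx(0.031)

    def test_large_ps_none_rejected(self):
        res = stats.bh_fdr([0.5, 0.6, 0.9], q=0.05)
        assert not res.rejected.any()

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(0, 1, 40)
        res = stats.bh_fdr(p, q=0.05)
        rej_ref, adj_ref, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
        assert np.allclose(res.adjusted, adj_ref, atol=1e-12)
        assert np.array_equal(res.rejected, rej_ref)

    def test_adjusted_monotone_in_rank(self, rng):
        p = rng.uniform(0, 1, 25)
        res = stats.bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(res.adjusted[order]) >= -1e-15)
        assert np.all(res.adjusted >= res.pvals - 1e-15)


class TestChannelwise:
    def test_null_fdr_controlled(self):
        rng = np.random.default_rng(3)
        false_hits = []
        for r in range(20):
            vals = rng.normal(0, 1, (30, 12))
            groups = np.repeat([0, 1], 15)
            out = stats.channelwise_group_test(vals, groups, n_perm=400,
                                               seed=r, q=0.05)
            false_hits.append(out["rejected"].mean())
        assert np.mean(false_hits) <= 0.05

    def test_injected_shift_detected(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(0, 1, (40, 10))
        groups = np.repeat([0, 1], 20)
        vals[groups == 1, 3] += 2.5
        out = stats.channelwise_group_test(vals, groups, n_perm=1000, seed=0)
        assert out["rejected"][3]
        assert out["rejected"].sum() <= 3

    def test_zero_channels_rejected(self):
        with pytest.raises(ParameterError):
            stats.channelwise_group_test(np.empty((10, 0)),
                                         np.repeat([0, 1], 5))
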