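import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import _oracles
from granet.exceptions import ValidationError
from granet.granger import (
    default_p_max,
    fit_restricted,
    fit_unrestricted,
    granger_statistic,
    granger_test,
    pairwise_causality,
    select_lag_aic,
)
from granet.preprocess import ExpressionMatrix
from granet.simulate import VARSpec, simulate_var


def ar1_series(n=12, a=0.5, x0=1.0):
    x = [x0]
    for _ in range(n - 1):
        x.append(a * x[-1])
    return np.asarray(x)


class TestFitRestricted:
    def test_exact_ar1(self):
        fit = fit_restricted(ar1_series(), p=1)
        assert fit.own_coefs[0] == pytest.approx(0.5)
        assert fit.rss == pytest.approx(0.0, abs=1e-20)
        assert not fit.degenerate

    def test_linear_recurrence(self):
        fit = fit_restricted(np.array([1.0, 2.0, 3.0, 4.0, 5.0]), p=1)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.own_coefs[0] == pytest.approx(1.0)
        assert fit.rss == pytest.approx(0.0, abs=1e-20)

    def test_alternating_series_normal_equations(self):
        # x_t on x_{t-1} for [1,2,1,2,1,2]: exact line through (1,2) and (2,1)
        fit = fit_restricted(np.array([1.0, 2.0, 1.0, 2.0, 1.0, 2.0]), p=1)
        assert fit.own_coefs[0] == pytest.approx(-1.0)
        assert fit.intercept == pytest.approx(3.0)
        assert fit.rss == pytest.approx(0.0, abs=1e-20)

    def test_constant_series_flagged_degenerate(self):
        fit = fit_restricted(np.full(10, 4.0), p=1)
        assert fit.degenerate

    def test_too_short_raises(self):
        with pytest.raises(ValidationError):
            fit_restricted(np.arange(5.0), p=2)

    def test_parameter_counts(self):
        x = np.random.default_rng(0).normal(size=30)
        assert fit_restricted(x, 3).n_params == 4
        assert fit_unrestricted(x, x[::-1], 3).n_params == 7


class TestFitUnrestricted:
    def test_zero_regressor_matches_restricted_rss(self, rng):
        x = rng.normal(size=40)
        unr = fit_unrestricted(x, np.zeros(40), p=2)
        res = fit_restricted(x, p=2)
        assert unr.rss == pytest.approx(res.rss)
        assert unr.degenerate  # zero columns are rank deficient, flagged not raised

    def test_perfect_cross_prediction(self, rng):
        y = rng.normal(size=50)
        x = np.concatenate([[0.0], y[:-1]])  # x_t = y_{t-1}
        fit = fit_unrestricted(x, y, p=1)
        assert fit.rss == pytest.approx(0.0, abs=1e-18)
        assert fit.cross_coefs[0] == pytest.approx(1.0)

    def test_nested_inequality_vs_independent_ols(self, rng):
        x, y = rng.normal(size=(2, 50))
        unr = fit_unrestricted(x, y, p=2)
        res = fit_restricted(x, p=2)
        assert unr.rss <= res.rss + 1e-12
        # independent oracle: normal-equation solve on the same design
        T, p = 50, 2
        X = np.column_stack(
            [np.ones(T - p)] + [x[p - i:T - i] for i in (1, 2)] + [y[p - i:T - i] for i in (1, 2)]
        )
        beta, rss = _oracles.ols_normal_equations(X, x[p:])
        assert unr.rss == pytest.approx(rss, abs=1e-8)
        assert np.allclose(np.r_[unr.intercept, unr.own_coefs, unr.cross_coefs], beta, atol=1e-8)

    @given(seed=st.integers(0, 10_000), p=st.integers(1, 3))
    @settings(max_examples=40, deadline=None)
    def test_nestedness_property(self, seed, p):
        r = np.random.default_rng(seed)
        x, y = r.normal(size=(2, 30))
        assert fit_unrestricted(x, y, p).rss <= fit_restricted(x, p).rss + 1e-10


class TestGrangerStatistic:
    def test_no_improvement_gives_zero(self):
        s = granger_statistic(2.5, 2.5, p=2, n_obs=30)
        assert s.statistic == 0.0 and s.p_value == pytest.approx(1.0)

    def test_direct_substitution(self):
        s = granger_statistic(3.0, 1.0, p=1, n_obs=12)
        assert s.statistic == pytest.approx(18.0)
        assert (s.df1, s.df2) == (1, 9)

    def test_f_quantile_inversion(self):
        crit = stats.f.ppf(0.95, 1, 9)
        rss1 = 1.0
        rss0 = rss1 + crit * rss1 / 9  # S == crit by construction
        s = granger_statistic(rss0, rss1, p=1, n_obs=12)
        assert s.p_value == pytest.approx(0.05, abs=1e-12)

    def test_perfect_fit_flag(self):
        with pytest.warns(UserWarning, match="perfect"):
            s = granger_statistic(1.0, 0.0, p=1, n_obs=12)
        assert np.isinf(s.statistic) and s.p_value == 0.0 and s.perfect_fit

    def test_negative_deficit_clamped(self):
        s = granger_statistic(1.0 - 1e-14, 1.0, p=1, n_obs=12)
        assert s.statistic == 0.0

    def test_monotone_p_value_in_statistic(self):
        stats_at = [granger_statistic(1.0 + d, 1.0, 2, 40).p_value for d in (0.1, 0.5, 2.0)]
        assert stats_at[0] > stats_at[1] > stats_at[2]

    def test_insufficient_dof_raises(self):
        with pytest.raises(ValidationError):
            granger_statistic(2.0, 1.0, p=3, n_obs=7)


class TestSelectLagAIC:
    def test_single_candidate(self, rng):
        x, y = rng.normal(size=(2, 30))
        assert select_lag_aic(x, y, p_max=1).p == 1

    def test_modal_lag_one_under_independence(self):
        r = np.random.default_rng(11)
        chosen = [select_lag_aic(r.normal(size=200), r.normal(size=200), 4).p for _ in range(100)]
        assert np.bincount(chosen).argmax() == 1

    def test_lag3_cross_term_recovered(self):
        spec = VARSpec(2, ((1, 1, 1, 0.4), (2, 2, 1, 0.4), (1, 2, 3, 0.8)))
        hits = 0
        for seed in range(100):
            s = simulate_var(spec, T=500, seed=seed)
            hits += select_lag_aic(s.data[0], s.data[1], 4).p >= 3
        assert hits >= 90

    def test_scanned_grid_minimum(self, rng):
        x, y = rng.normal(size=(2, 80))
        rec = select_lag_aic(x, y, p_max=4)
        assert rec.aic == min(rec.scanned.values())
        assert rec.m == 2 and rec.n == 76


class TestGrangerTest:
    def test_lagged_copy_rejects(self, rng):
        y = rng.normal(size=100)
        x = np.concatenate([[0.0], y[:-1]])
        result = granger_test(x, y, alpha=0.05)
        assert result.reject

    def test_default_alpha_is_005(self, rng):
        result = granger_test(*rng.normal(size=(2, 60)))
        assert result.alpha == 0.05

    def test_reject_iff_pvalue_below_alpha(self, rng):
        for _ in range(20):
            r = granger_test(*rng.normal(size=(2, 50)))
            assert r.reject == (r.p_value < r.alpha)

    def test_type_one_error_light(self):
        # light version of the full 2000-pair calibration in the acceptance suite
        r = np.random.default_rng(5)
        rejections = sum(
            granger_test(r.normal(size=100), r.normal(size=100), p_max=4).reject
            for _ in range(400)
        )
        assert 0.02 <= rejections / 400 <= 0.10

    def test_degenerate_pair_is_no_edge_not_crash(self):
        result = granger_test(np.full(40, 3.0), np.full(40, 5.0))
        assert result.degenerate and not result.reject and result.statistic == 0.0

    def test_invalid_alpha(self, rng):
        with pytest.raises(ValidationError):
            granger_test(*rng.normal(size=(2, 40)), alpha=1.5)

    def test_fixed_lag_respected(self, rng):
        result = granger_test(*rng.normal(size=(2, 60)), p=3)
        assert result.lag == 3 and result.df1 == 3

    def test_default_p_max_short_series(self):
        assert default_p_max(23) == 4  # 21 differenced points of a 23-point series
        assert default_p_max(10) == 2
        assert default_p_max(6) == 1


class TestPairwiseCausality:
    def test_fifteen_genes_do_210_tests(self, rng):
        d = pairwise_causality(rng.normal(size=(15, 30)))
        assert d.n_tests == 210

    def test_diagonal_zero(self, rng):
        d = pairwise_causality(rng.normal(size=(5, 40)))
        assert np.all(np.diag(d.values) == 0.0)

    def test_strengths_are_rejected_statistics(self, rng):
        m = ExpressionMatrix([f"g{i}" for i in range(4)], rng.normal(size=(4, 60)))
        d = pairwise_causality(m, alpha=0.05, lag=2)
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                r = granger_test(m.values[i], m.values[j], p=2)
                expected = r.statistic if r.reject else 0.0
                assert d.values[i, j] == pytest.approx(expected)

    def test_degenerate_rows_recorded_as_zero(self, rng):
        data = np.vstack([np.full(40, 1.0), rng.normal(size=(2, 40))])
        d = pairwise_causality(data)
        assert np.all(d.values[:, 0] == 0.0) and np.all(d.values[0, :] == 0.0)

    def test_single_gene_rejected(self):
        with pytest.raises(ValidationError):
            pairwise_causality(np.zeros((1, 30)))
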