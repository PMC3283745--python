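"""Max-T inference: quantiles, degrees of freedom, intervals, full test."""

import numpy as np
import pytest
from scipy import stats

from npmct import (
    GroupedSample,
    equicoordinate_quantile,
    marcus_matrix,
    mctp_test,
    relative_effects,
    satterthwaite_df,
    simultaneous_ci,
    studentize,
)
from npmct.mctp import mvt_box_prob
from npmct.ranks import EffectEstimate

from conftest import random_grouped


class TestEquicoordinateQuantile:
    def test_identity_correlation_closed_form(self):
        # (2 Phi(z) - 1)^3 = 0.95
        z = equicoordinate_quantile(np.eye(3), np.inf, 0.05)
        assert z == pytest.approx(stats.norm.ppf((1 + 0.95 ** (1 / 3)) / 2), abs=1e-3)

    def test_perfect_correlation_collapses_to_univariate(self):
        z = equicoordinate_quantile(np.ones((3, 3)), np.inf, 0.05)
        assert z == pytest.approx(1.959964, abs=1e-3)
        zt = equicoordinate_quantile(np.ones((3, 3)), 30, 0.05)
        assert zt == pytest.approx(stats.t.ppf(0.975, 30), abs=2e-3)

    def test_alpha_monotonicity(self):
        R = np.array([[1, 0.5, 0.3], [0.5, 1, 0.6], [0.3, 0.6, 1.0]])
        assert equicoordinate_quantile(R, 20, 0.01) > equicoordinate_quantile(R, 20, 0.05)

    def test_invalid_correlation_rejected(self):
        with pytest.raises(ValueError):
            equicoordinate_quantile(np.array([[1.0, 2.0], [2.0, 1.0]]), 10, 0.05)

    def test_one_sided_smaller_than_two_sided(self):
        R = np.eye(3)
        assert equicoordinate_quantile(R, 20, 0.05, two_sided=False) < equicoordinate_quantile(
            R, 20, 0.05
        )


def test_box_prob_identity_against_independent_oracles():
    # normal case: coordinates are independent, the probability factorizes
    for b in (1.0, 2.0, 2.8):
        assert mvt_box_prob(b, np.eye(3), None) == pytest.approx(
            (2 * stats.norm.cdf(b) - 1) ** 3, abs=2e-4
        )
    # t case: coordinates share the chi denominator; integrate it out:
    # P(max|T| <= b) = E[(2 Phi(b S) - 1)^3], S ~ chi_nu / sqrt(nu)
    for df in (10, 60):
        for b in (1.0, 2.0):
            s = np.linspace(1e-6, 4.0, 20_001)
            dens = stats.chi(df).pdf(s * np.sqrt(df)) * np.sqrt(df)
            oracle = np.trapezoid((2 * stats.norm.cdf(b * s) - 1) ** 3 * dens, s)
            assert mvt_box_prob(b, np.eye(3), df) == pytest.approx(oracle, abs=5e-4)


def _diagonal_estimate(V, contribs, n):
    return EffectEstimate(
        p_hat=np.zeros(3),
        w_hat=np.full((3, 3), 0.5),
        pseudo_ranks=np.zeros(int(np.sum(n))),
        n=np.asarray(n),
        N=int(np.sum(n)),
        V_hat=V,
        group_contrib=contribs,
    )


def test_studentize_correlation_for_spherical_covariance():
    spec = marcus_matrix(10, 10, 10)
    est = _diagonal_estimate(np.eye(3), [np.eye(3) / 3] * 3, [10, 10, 10])
    T, se, R = studentize(np.zeros(3), spec, est, 30)
    np.testing.assert_array_equal(T, np.zeros(3))
    # c_dom' c_add / (|c_dom| |c_add|) = 1.5 / sqrt(1.5 * 2)
    assert R[0, 1] == pytest.approx(1.5 / np.sqrt(3.0), abs=1e-12)


def test_studentize_scale_invariance(rng):
    gs = random_grouped(rng, max_n=15)
    spec = marcus_matrix(*gs.n)
    eff = relative_effects(gs)
    delta = spec.matrix @ eff.p_hat
    T1, se1, R1 = studentize(delta, spec, eff, gs.N)
    eff2 = relative_effects(gs.transform(lambda x: 2.0 * x))
    T2, se2, R2 = studentize(spec.matrix @ eff2.p_hat, spec, eff2, gs.N)
    assert np.array_equal(T1, T2) and np.array_equal(R1, R2)


class TestSatterthwaite:
    def test_equal_contributions_give_pooled_df(self):
        spec = marcus_matrix(11, 11, 11)
        df = satterthwaite_df(spec, [np.eye(3)] * 3, [11, 11, 11])
        assert df == pytest.approx(30.0)

    def test_single_group_dominates(self):
        spec = marcus_matrix(11, 5, 7)
        df = satterthwaite_df(spec, [np.eye(3), np.zeros((3, 3)), np.zeros((3, 3))], [11, 5, 7])
        assert df == pytest.approx(10.0)

    def test_scale_invariance(self):
        spec = marcus_matrix(8, 12, 6)
        contribs = [np.diag([0.3, 0.1, 0.2]), np.eye(3) * 0.05, np.diag([0.2, 0.4, 0.1])]
        a = satterthwaite_df(spec, contribs, [8, 12, 6])
        b = satterthwaite_df(spec, [17.0 * c for c in contribs], [8, 12, 6])
        assert a == pytest.approx(b, rel=1e-12)

    def test_all_degenerate_returns_inf(self):
        spec = marcus_matrix(5, 5, 5)
        assert np.isinf(satterthwaite_df(spec, [np.zeros((3, 3))] * 3, [5, 5, 5]))


class TestSimultaneousCI:
    def test_fisher_interval_at_zero(self):
        lo, hi = simultaneous_ci([0.0], [0.1], 2.0, method="fisher")
        assert lo[0] == pytest.approx(-np.tanh(0.2), abs=1e-12)
        assert hi[0] == pytest.approx(np.tanh(0.2), abs=1e-12)

    def test_zero_se_degenerates_both_methods(self):
        for method in ("plain", "fisher"):
            lo, hi = simultaneous_ci([0.3], [0.0], 2.0, method=method)
            assert lo[0] == hi[0] == 0.3

    def test_plain_may_leave_range_fisher_does_not(self):
        lo_p, hi_p = simultaneous_ci([0.9], [0.15], 2.0, method="plain")
        lo_f, hi_f = simultaneous_ci([0.9], [0.15], 2.0, method="fisher")
        assert hi_p[0] > 1.0
        assert -1.0 < lo_f[0] < hi_f[0] < 1.0

    def test_fisher_reduces_to_plain_for_small_se(self):
        d, se = np.array([0.2]), np.array([1e-5])
        lo_p, hi_p = simultaneous_ci(d, se, 2.0, method="plain")
        lo_f, hi_f = simultaneous_ci(d, se, 2.0, method="fisher")
        assert hi_f[0] - hi_p[0] == pytest.approx(0.0, abs=1e-8)


class TestMctpTest:
    def test_strong_separation_all_outputs_finite(self):
        gs = GroupedSample((np.array([1.0, 2]), np.array([3.0, 4]), np.array([1000.0, 1001])))
        res = mctp_test(gs)
        for arr in (res.estimate, res.se, res.statistic, res.lower, res.upper, res.p_adjusted):
            assert np.all(np.isfinite(arr))

    def test_total_ties_carry_no_evidence(self):
        gs = GroupedSample(tuple(np.full(5, 3.0) for _ in range(3)))
        res = mctp_test(gs)
        assert np.all(res.degenerate)
        assert np.all(res.p_adjusted == 1.0) and not res.global_reject

    def test_monotone_transform_leaves_inference_bit_identical(self, rng):
        gs = random_grouped(rng, max_n=15, tied=True)
        for interval in ("plain", "fisher"):
            a = mctp_test(gs, interval=interval)
            b = mctp_test(gs.transform(np.exp), interval=interval)
            for x, y in (
                (a.estimate, b.estimate),
                (a.statistic, b.statistic),
                (a.lower, b.lower),
                (a.upper, b.upper),
                (a.p_adjusted, b.p_adjusted),
            ):
                assert np.array_equal(x, y)
            assert a.quantile == b.quantile and a.df == b.df

    def test_adjusted_p_never_below_marginal_t_p(self, rng):
        for _ in range(10):
            gs = random_grouped(rng, max_n=20)
            res = mctp_test(gs, interval="plain")
            marginal = 2 * stats.t.sf(np.abs(res.statistic), res.df)
            assert np.all(res.p_adjusted >= marginal - 5e-4)

    def test_sidak_limit_for_identity_correlation(self):
        # in the normal limit independent statistics give the Sidak product
        for t in (1.3, 2.1, 0.4):
            padj = 1.0 - mvt_box_prob(t, np.eye(3), None)
            marg = 2 * stats.norm.sf(t)
            assert padj == pytest.approx(1 - (1 - marg) ** 3, abs=5e-4)

    def test_compatibility_ci_vs_adjusted_p(self, rng):
        for _ in range(40):
            gs = random_grouped(rng, max_n=12, tied=bool(rng.integers(2)))
            for interval in ("plain", "fisher"):
                res = mctp_test(gs, interval=interval)
                excludes = (res.lower > res.null_value) | (res.upper < res.null_value)
                np.testing.assert_array_equal(excludes, res.p_adjusted < res.alpha)

    def test_normal_approx_uses_infinite_df(self, rng):
        gs = random_grouped(rng, max_n=15)
        res = mctp_test(gs, approx="normal")
        assert np.isinf(res.df)

    def test_global_decision_is_min_p_rule(self, rng):
        gs = random_grouped(rng, max_n=15)
        res = mctp_test(gs)
        assert res.p_global == res.p_adjusted.min()
        assert res.global_reject == (res.p_global < res.alpha)

    def test_small_group_rejected(self):
        gs = GroupedSample((np.array([1.0, 2, 3]), np.array([4.0]), np.array([5.0, 6])))
        with pytest.raises(ValueError, match="variance not estimable"):
            mctp_test(gs)
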