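import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from vqtl.exceptions import (
    CollinearGenotypeError,
    DegenerateResidualsError,
    GroupingError,
    InfeasibleVarianceError,
)
from vqtl.het_tests import (
    HetTestResult,
    VarParams,
    fit_chisq_regression,
    fit_lmm,
    fit_null_variance,
    fit_ols_squared,
    fit_variance_component,
    levene_bf,
    loglik_chisq_form,
    loglik_variance_model,
    mixture_pvalue,
    pseudo_r2,
)
from vqtl.mean_model import ResidualSet, fit_mean_model
from vqtl.simulate import simulate_random_slope_trait


def _random_resid(rng, n=500, maf=0.3, scale=1.0):
    g = rng.binomial(2, maf, n).astype(float)
    e = rng.standard_normal(n) * scale
    e -= e.mean()
    return ResidualSet(e, n, g)


class TestLoglik:
    def test_zero_residuals_unit_variance(self):
        resid = ResidualSet(np.zeros(2), 2, np.zeros(2))
        ll = loglik_variance_model(resid, VarParams(1.0, 0.0, 0.0))
        assert ll == pytest.approx(-np.log(2 * np.pi), abs=1e-12)

    def test_agrees_with_gamma_density_route(self, rng):
        # e^2 = v(G)*chi2_1 <=> e^2 ~ Gamma(1/2, scale 2v); with the e -> e^2
        # Jacobian the two likelihoods are identical
        resid = _random_resid(rng)
        tau = VarParams(1.2, 0.15, 0.3)
        assert loglik_variance_model(resid, tau) == pytest.approx(
            loglik_chisq_form(resid, tau), abs=1e-10
        )

    def test_infeasible_variance_signalled(self, rng):
        resid = _random_resid(rng)
        with pytest.raises(InfeasibleVarianceError):
            loglik_variance_model(resid, VarParams(0.1, -0.5, 0.0))

    def test_null_fit_closed_form(self):
        resid = ResidualSet(np.array([1.0, -1.0, 2.0, -2.0]), 4, np.zeros(4))
        tau1, ll = fit_null_variance(resid)
        assert tau1 == pytest.approx(2.5)
        assert ll == pytest.approx(-7.5086, abs=5e-4)

    def test_null_fit_scale_equivariance(self, rng):
        resid = _random_resid(rng)
        tau1, _ = fit_null_variance(resid)
        scaled = ResidualSet(3.0 * resid.residuals, resid.n, resid.genotype)
        tau1_scaled, _ = fit_null_variance(scaled)
        assert tau1_scaled == pytest.approx(9.0 * tau1, rel=1e-12)


class TestSaturatedOracle:
    """Hard-called genotypes saturate the quadratic variance law, so the ML
    fitted variances are the within-genotype means of e^2 and tau has a
    closed form solved from the three group means."""

    def test_ols_recovers_group_means(self, saturated_residuals):
        res = fit_ols_squared(saturated_residuals)
        assert (res.tau.tau1, res.tau.tau2, res.tau.tau3) == pytest.approx(
            (2.0, 0.5, 1.0), abs=1e-10
        )

    def test_chisq_regression_same_point_and_lrt(self, saturated_residuals):
        res = fit_chisq_regression(saturated_residuals)
        assert (res.tau.tau1, res.tau.tau2, res.tau.tau3) == pytest.approx(
            (2.0, 0.5, 1.0), abs=1e-6
        )
        # LRT = 2*[ln(s0/2)+ln(s0/4)+ln(s0/8)], s0 = 14/3
        s0 = 14.0 / 3.0
        expect = 2.0 * (np.log(s0 / 2) + np.log(s0 / 4) + np.log(s0 / 8))
        assert res.lrt == pytest.approx(expect, abs=1e-8)
        assert res.p_het == pytest.approx(np.exp(-expect / 2), abs=1e-8)
        assert res.converged

    def test_vc_constraint_inactive_same_point(self, saturated_residuals):
        res = fit_variance_component(saturated_residuals)
        assert (res.tau.tau1, res.tau.tau2, res.tau.tau3) == pytest.approx(
            (2.0, 0.5, 1.0), abs=1e-6
        )
        q = res.lrt
        mix = 0.5 * stats.chi2.sf(q, 1) + 0.5 * np.exp(-q / 2)
        assert res.p_het == pytest.approx(mix, abs=1e-10)
        assert res.p_het == pytest.approx(0.483, abs=1e-3)


class TestOlsSquared:
    def test_constant_squared_residuals_give_null(self):
        e = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        g = np.array([0.0, 0.0, 1.0, 1.0, 2.0, 2.0])
        res = fit_ols_squared(ResidualSet(e, 6, g))
        assert res.lrt == 0.0
        assert res.p_het == pytest.approx(1.0)

    def test_two_genotype_values_collinear(self, rng):
        e = rng.standard_normal(40)
        g = np.repeat([0.0, 1.0], 20)
        with pytest.raises(CollinearGenotypeError):
            fit_ols_squared(ResidualSet(e, 40, g))

    def test_consistent_under_null(self, rng):
        resid = _random_resid(rng, n=60_000)
        res = fit_ols_squared(resid)
        assert abs(res.tau.tau2) < 0.05
        assert abs(res.tau.tau3) < 0.05


class TestChisqRegression:
    def test_ascent_from_ols_start(self, rng):
        resid = _random_resid(rng, n=800)
        start = fit_ols_squared(resid).tau
        res = fit_chisq_regression(resid, start=start)
        ll_start = loglik_variance_model(resid, start)
        assert res.loglik_alt >= ll_start - 1e-9

    def test_infeasible_start_repaired(self, rng):
        resid = _random_resid(rng, n=400)
        bad = VarParams(0.01, -2.0, 0.0)  # v(g) < 0 at g > 0
        res = fit_chisq_regression(resid, start=bad)
        assert res.converged
        assert res.tau.variance(resid.genotype).min() > 0

    def test_null_distribution_is_chi2_2df(self):
        # under homoscedastic truth the LRT should look chi2(2 df)
        rng = np.random.default_rng(77)
        lrts = []
        for _ in range(300):
            resid = _random_resid(rng, n=400)
            lrts.append(fit_chisq_regression(resid).lrt)
        ks = stats.kstest(lrts, stats.chi2(2).cdf)
        assert ks.pvalue > 1e-3

    def test_degenerate_residuals_rejected(self):
        resid = ResidualSet(np.zeros(10), 10, np.arange(10) % 3, degenerate=True)
        with pytest.raises(DegenerateResidualsError):
            fit_chisq_regression(resid)


class TestVarianceComponent:
    def test_lrt_never_exceeds_unconstrained(self, rng):
        for _ in range(25):
            resid = _random_resid(rng, n=300)
            lrt_c = fit_chisq_regression(resid).lrt
            lrt_v = fit_variance_component(resid).lrt
            assert lrt_v <= lrt_c + 1e-8

    def test_boundary_solution_is_psd(self, rng):
        hits = 0
        for _ in range(30):
            resid = _random_resid(rng, n=200)
            res = fit_variance_component(resid)
            assert res.tau.is_psd(tol=1e-8)
            chi = fit_chisq_regression(resid)
            if not chi.tau.is_psd(tol=1e-12):
                hits += 1
                assert res.loglik_alt <= chi.loglik_alt + 1e-8
        assert hits > 0  # the null data do exercise the boundary path

    def test_tau3_recovery(self):
        sigma2 = 2.0
        y, g = simulate_random_slope_trait(40_000, 0.5, -0.475, sigma2, seed=5)
        _, resid = fit_mean_model(y, np.ones((len(y), 1)), g)
        res = fit_variance_component(resid)
        assert res.tau.tau3 == pytest.approx(sigma2, rel=0.15)
        assert abs(res.tau.tau2) < 0.15


class TestLmm:
    def test_degenerate_exact_fit_errors(self):
        g = np.array([0.0, 1.0, 2.0, 1.0, 0.0, 2.0])
        y = 3.0 + 2.0 * g
        with pytest.raises(DegenerateResidualsError):
            fit_lmm(y, np.ones((6, 1)), g)

    def test_reduces_to_ols_under_homoscedasticity(self, rng):
        n = 4000
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        g = rng.binomial(2, 0.3, n).astype(float)
        y = X @ [1.0, 0.5] + 0.2 * g + rng.standard_normal(n)
        beta, res = fit_lmm(y, X, g)
        ols_beta, _, _, _ = np.linalg.lstsq(np.column_stack([X, g]), y, rcond=None)
        # the O(n^-1/2) noise in tau-hat perturbs the WLS weights, so the
        # agreement is to a small fraction of the coefficient SE (~1/sqrt(n)),
        # not to machine precision
        np.testing.assert_allclose(beta, ols_beta, atol=0.05 / np.sqrt(n))
        assert abs(res.tau.tau2) < 0.05 and abs(res.tau.tau3) < 0.05

    def test_matches_vc_on_heteroscedastic_data(self):
        y, g = simulate_random_slope_trait(5000, 0.3, -0.5, 2.0, seed=9)
        X = np.ones((5000, 1))
        _, lmm = fit_lmm(y, X, g)
        _, resid = fit_mean_model(y, X, g)
        vc = fit_variance_component(resid)
        assert lmm.lrt == pytest.approx(vc.lrt, rel=0.01)
        assert lmm.p_het == pytest.approx(vc.p_het, rel=0.1)


class TestMixtureAndPseudoR2:
    def test_closed_form_values(self):
        assert mixture_pvalue(0.0) == 1.0
        assert mixture_pvalue(3.841) == pytest.approx(0.0982, abs=1e-4)
        assert pseudo_r2(0.0, 100) == 0.0
        assert pseudo_r2(10.0, 1000) == pytest.approx(0.00995, abs=1e-5)

    @given(st.floats(min_value=1e-6, max_value=60.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_mixture_between_ordered_survivals(self, q):
        p = mixture_pvalue(q)
        assert stats.chi2.sf(q, 1) <= p <= stats.chi2.sf(q, 2)

    @given(
        st.floats(min_value=0.0, max_value=50.0),
        st.floats(min_value=1e-3, max_value=10.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_mixture_strictly_decreasing(self, q, dq):
        assert mixture_pvalue(q + dq) < mixture_pvalue(q)

    @given(
        st.floats(min_value=0.0, max_value=50.0),
        st.floats(min_value=1e-3, max_value=10.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_pseudo_r2_monotone_in_lrt(self, lrt, dl):
        assert pseudo_r2(lrt + dl, 500) > pseudo_r2(lrt, 500)

    def test_negative_statistic_rejected(self):
        with pytest.raises(ValueError):
            mixture_pvalue(-0.1)


class TestLeveneBrownForsythe:
    def test_identical_groups_give_f_zero(self):
        e = np.array([0.0, 1.0, 2.0, 0.0, 1.0, 2.0])
        hc = np.array([0, 0, 0, 1, 1, 1])
        res = levene_bf(ResidualSet(e, 6, np.asarray(hc, float)), hc)
        assert res.lrt == 0.0 and res.p_het == pytest.approx(1.0)

    def test_hand_worked_two_group_anova(self):
        # A={0,0,2,2} (median 1, z=1,1,1,1), B={0,0,0,4} (median 0, z=0,0,0,4):
        # both group means of z are 1, so the between-group SS vanishes
        e = np.array([0.0, 0.0, 2.0, 2.0, 0.0, 0.0, 0.0, 4.0])
        hc = np.array([0, 0, 0, 0, 2, 2, 2, 2])
        res = levene_bf(ResidualSet(e, 8, np.asarray(hc, float)), hc)
        assert res.lrt == pytest.approx(0.0, abs=1e-12)
        assert res.p_het == pytest.approx(1.0)

    def test_matches_scipy_reference(self, rng):
        g = rng.binomial(2, 0.4, 300)
        e = rng.standard_normal(300) * (1.0 + 0.3 * g)
        res = levene_bf(ResidualSet(e, 300, g.astype(float)), g)
        groups = [e[g == k] for k in (0, 1, 2)]
        ref_f, ref_p = stats.levene(*groups, center="median")
        assert res.lrt == pytest.approx(ref_f, abs=1e-10)
        assert res.p_het == pytest.approx(ref_p, abs=1e-10)

    def test_small_groups_dropped_then_error(self, rng):
        e = rng.standard_normal(6)
        hc = np.array([0, 0, 0, 0, 0, 2])  # the g=2 group has one member
        with pytest.raises(GroupingError):
            levene_bf(ResidualSet(e, 6, hc.astype(float)), hc)
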