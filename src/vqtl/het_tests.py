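r"""Heteroscedasticity (variance-QTL) tests.

A variance QTL is a variant whose genotype G is associated with the
*variance* of a quantitative trait rather than (only) its mean. Modelling
the per-individual trait variance as a quadratic in the dosage,

    v(G) = tau1 + 2*tau2*G + tau3*G**2,

where (tau1, tau2; tau2, tau3) is the covariance matrix of two latent
random effects (an environmental intercept gamma1, absorbing the error, and
a genotype-modulating slope gamma2), the null of no heteroscedasticity is
H0: tau2 = tau3 = 0. Four tests of H0 are implemented, all operating on the
residuals e of the mean model (see :mod:`vqtl.mean_model`):

``ols``
    Quadratic extension of the Breusch-Pagan test: OLS of e^2 on
    (1, 2G, G^2); Gaussian LRT ``n*log(RSS0/RSS1)`` against chi2 with 2 df.
    tau is unconstrained and no distribution is assumed for the random
    effects.
``chi2``
    Chi-square regression: e^2 = v(G) * chi2_1, i.e. exact ML of the
    normal-residual likelihood over unconstrained tau, Newton-Raphson with
    step-halving, started from the ``ols`` estimates; LRT against chi2 2 df.
    The likelihood coincides with that of the variance-component model and
    with a gamma regression of e^2 with shape 1/2 and scale 2*v(G).
``vc``
    Variance-component model: same likelihood with (tau1, tau2; tau2, tau3)
    constrained positive semidefinite (bivariate-normal random effects);
    LRT against the 0.5:0.5 mixture of chi2 with 1 and 2 df (boundary null).
``lmm``
    Joint ML of the linear mixed model y = X*beta + betaG*G + gamma1 +
    gamma2*G: fixed effects profiled out by weighted least squares, tau
    updated by Newton-Raphson on the profiled likelihood; same PSD
    constraint and mixture null as ``vc``.

`levene_bf` (Brown-Forsythe on hard-called genotype groups) is included as
the standard nonparametric comparison.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy import stats

from .exceptions import (
    CollinearGenotypeError,
    DegenerateResidualsError,
    GroupingError,
    InfeasibleVarianceError,
)
from .mean_model import ResidualSet, fit_mean_model

__all__ = [
    "VarParams",
    "HetTestResult",
    "loglik_variance_model",
    "loglik_chisq_form",
    "fit_null_variance",
    "fit_ols_squared",
    "fit_chisq_regression",
    "fit_variance_component",
    "fit_lmm",
    "mixture_pvalue",
    "pseudo_r2",
    "levene_bf",
]

MAX_ITER = 50
LL_TOL = 1e-8
MAX_HALVINGS = 20
# floor for v(g) relative to var(e) when repairing infeasible starts
FEASIBILITY_FLOOR = 1e-8


@dataclass
class VarParams:
    """Variance-law parameters: v(G) = tau1 + 2*tau2*G + tau3*G^2.

    ``psd_constrained`` records whether the estimate was obtained under the
    positive-semidefiniteness constraint on (tau1, tau2; tau2, tau3).
    """

    tau1: float
    tau2: float
    tau3: float
    psd_constrained: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([self.tau1, self.tau2, self.tau3], dtype=float)

    def variance(self, g: np.ndarray) -> np.ndarray:
        g = np.asarray(g, dtype=float)
        return self.tau1 + 2.0 * self.tau2 * g + self.tau3 * g * g

    def is_psd(self, tol: float = 1e-10) -> bool:
        scale = max(1.0, self.tau1 * self.tau1)
        det = self.tau1 * self.tau3 - self.tau2 * self.tau2
        return (
            self.tau1 >= -tol
            and self.tau3 >= -tol * max(1.0, abs(self.tau1))
            and det >= -tol * scale
        )


@dataclass
class HetTestResult:
    """Outcome of one heteroscedasticity test on one variant."""

    method: str
    tau: Optional[VarParams]
    loglik_null: float
    loglik_alt: float
    lrt: float
    df_rule: str
    p_het: float
    r2_het: float
    converged: bool
    n_iter: int


# ---------------------------------------------------------------------------
# likelihood


def _vdesign(g: np.ndarray) -> np.ndarray:
    """Design of the variance law: columns (1, 2G, G^2) so coefs are tau."""
    g = np.asarray(g, dtype=float)
    return np.column_stack([np.ones_like(g), 2.0 * g, g * g])


def _ll_normal(e2: np.ndarray, v: np.ndarray) -> float:
    return float(-0.5 * np.sum(np.log(2.0 * np.pi * v) + e2 / v))


def _resid_arrays(resid: ResidualSet, g=None) -> tuple[np.ndarray, np.ndarray]:
    e = np.asarray(resid.residuals, dtype=float)
    g = np.asarray(resid.genotype if g is None else g, dtype=float)
    if e.shape != g.shape:
        raise ValueError("residuals and genotype must be aligned")
    return e, g


def loglik_variance_model(resid: ResidualSet, tau: VarParams, g=None) -> float:
    """Gaussian log-likelihood of the residuals under v(G) = tau1+2*tau2*G+tau3*G^2.

    sum_i [ -0.5*log(2*pi*v(g_i)) - e_i^2 / (2*v(g_i)) ]. Raises
    :class:`InfeasibleVarianceError` if any v(g_i) <= 0.
    """
    e, g = _resid_arrays(resid, g)
    v = tau.variance(g)
    if np.any(v <= 0):
        raise InfeasibleVarianceError("v(g) <= 0 at an observed genotype")
    return _ll_normal(e * e, v)


def loglik_chisq_form(resid: ResidualSet, tau: VarParams, g=None) -> float:
    """The same likelihood computed via the chi-square-regression route.

    e^2 = v(G) * chi2_1 means e^2 is gamma with shape 1/2 and scale 2*v(G);
    adding the Jacobian log|e| of the e -> e^2 change of variable gives the
    density of e itself, so this must agree with
    :func:`loglik_variance_model` at every feasible tau. Requires nonzero
    residuals (the gamma density diverges at 0).
    """
    e, g = _resid_arrays(resid, g)
    if np.any(e == 0):
        raise ValueError("chi-square-form likelihood requires nonzero residuals")
    v = tau.variance(g)
    if np.any(v <= 0):
        raise InfeasibleVarianceError("v(g) <= 0 at an observed genotype")
    return float(
        np.sum(stats.gamma.logpdf(e * e, a=0.5, scale=2.0 * v))
        + np.sum(np.log(np.abs(e)))
    )


def fit_null_variance(resid: ResidualSet) -> tuple[float, float]:
    """ML under H0 (homoscedastic zero-mean normal): tau1 = mean(e^2).

    Returns (tau1_hat, loglik at tau1_hat).
    """
    e = np.asarray(resid.residuals, dtype=float)
    if e.size < 2:
        raise ValueError("need at least two residuals")
    tau1 = float(np.mean(e * e))
    if tau1 <= 0:
        raise DegenerateResidualsError("all residuals are zero")
    n = e.size
    ll = -0.5 * n * (np.log(2.0 * np.pi * tau1) + 1.0)
    return tau1, float(ll)


# ---------------------------------------------------------------------------
# Newton-Raphson machinery


def _newton_ascent(
    theta0: np.ndarray,
    loglik: Callable[[np.ndarray], float],
    grad_hess: Callable[[np.ndarray], tuple[np.ndarray, np.ndarray]],
    feasible: Callable[[np.ndarray], bool],
    max_iter: int = MAX_ITER,
    tol: float = LL_TOL,
) -> tuple[np.ndarray, float, bool, int]:
    """Maximise ``loglik`` by Newton steps with step-halving.

    ``grad_hess`` returns the gradient and Hessian at theta. A step is
    accepted only if it stays feasible and does not decrease the
    log-likelihood; convergence when the improvement drops below ``tol``.
    """
    theta = np.asarray(theta0, dtype=float).copy()
    ll = loglik(theta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        grad, hess = grad_hess(theta)
        try:
            step = np.linalg.solve(hess, -grad)
        except np.linalg.LinAlgError:
            step = np.zeros_like(grad)
        if not np.all(np.isfinite(step)) or float(grad @ step) <= 0:
            # Hessian not usable as an ascent metric here; fall back to a
            # conservatively scaled gradient step.
            scale = np.max(np.abs(hess)) + 1e-12
            step = grad / scale
        t = 1.0
        accepted = False
        ll_new = ll
        for _ in range(MAX_HALVINGS + 1):
            cand = theta + t * step
            if feasible(cand):
                ll_cand = loglik(cand)
                if np.isfinite(ll_cand) and ll_cand >= ll:
                    accepted = True
                    ll_new = ll_cand
                    theta_new = cand
                    break
            t *= 0.5
        if not accepted:
            break
        dll = ll_new - ll
        theta, ll = theta_new, ll_new
        if dll < tol:
            converged = True
            break
    return theta, ll, converged, it


def _repair_start(tau: VarParams, g: np.ndarray, var_e: float) -> np.ndarray:
    """Inflate tau1 until min v(g) clears the feasibility floor."""
    theta = tau.as_array()
    floor = FEASIBILITY_FLOOR * max(var_e, np.finfo(float).tiny)
    vmin = float(np.min(_vdesign(g) @ theta))
    if vmin < floor:
        theta[0] += floor - vmin
    return theta


def _fit_unconstrained(
    e2: np.ndarray, g: np.ndarray, theta0: np.ndarray
) -> tuple[np.ndarray, float, bool, int]:
    U = _vdesign(g)

    def loglik(theta: np.ndarray) -> float:
        return _ll_normal(e2, U @ theta)

    def grad_hess(theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        v = U @ theta
        r = e2 / v
        grad = U.T @ (0.5 * (r - 1.0) / v)
        h = (0.5 - r) / (v * v)
        hess = (U * h[:, None]).T @ U
        return grad, hess

    def feasible(theta: np.ndarray) -> bool:
        return bool(np.min(U @ theta) > 0)

    return _newton_ascent(theta0, loglik, grad_hess, feasible)


def _fit_rank1(
    e2: np.ndarray, g: np.ndarray, ab0: np.ndarray
) -> tuple[np.ndarray, float, bool, int]:
    """ML on the PSD boundary: tau = (a^2, a*b, b^2), so v(g) = (a + b*g)^2."""
    M = np.column_stack([np.ones_like(g), g])

    def loglik(ab: np.ndarray) -> float:
        w = M @ ab
        return _ll_normal(e2, w * w)

    def grad_hess(ab: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        w = M @ ab
        grad = M.T @ (e2 / w**3 - 1.0 / w)
        h = 1.0 / w**2 - 3.0 * e2 / w**4
        hess = (M * h[:, None]).T @ M
        return grad, hess

    def feasible(ab: np.ndarray) -> bool:
        return bool(np.min(M @ ab) > 0)

    return _newton_ascent(ab0, loglik, grad_hess, feasible)


def _rank1_starts(theta_u: np.ndarray, tau1_null: float, g: np.ndarray) -> list[np.ndarray]:
    """Candidate (a, b) starts for the boundary fit."""
    starts = [np.array([np.sqrt(tau1_null), 0.0])]
    a = np.sqrt(max(theta_u[0], FEASIBILITY_FLOOR * tau1_null, np.finfo(float).tiny))
    b = theta_u[1] / a
    # shrink b until w = a + b*g stays positive on the observed support
    for _ in range(40):
        if np.min(a + b * g) > 0:
            starts.append(np.array([a, b]))
            break
        b *= 0.5
    return starts


# ---------------------------------------------------------------------------
# the four tests


def _check_testable(resid: ResidualSet) -> None:
    if resid.degenerate:
        raise DegenerateResidualsError(
            "zero residual variance; heteroscedasticity tests undefined"
        )


def fit_ols_squared(resid: ResidualSet, g=None) -> HetTestResult:
    """Quadratic Breusch-Pagan: OLS of e^2 on (1, 2G, G^2).

    The Gaussian LRT n*log(RSS0/RSS1) against the intercept-only model is
    referred to chi2 with 2 df. tau estimates are unconstrained.
    """
    _check_testable(resid)
    e, g = _resid_arrays(resid, g)
    if np.unique(g).size < 3:
        raise CollinearGenotypeError(
            "G and G^2 collinear: fewer than 3 distinct genotype values"
        )
    e2 = e * e
    n = e2.size
    U = _vdesign(g)
    coef, _, rank, _ = np.linalg.lstsq(U, e2, rcond=None)
    if rank < 3:
        raise CollinearGenotypeError("variance design is rank deficient")
    rss1 = float(np.sum((e2 - U @ coef) ** 2))
    rss0 = float(np.sum((e2 - np.mean(e2)) ** 2))
    if rss0 <= 0 or rss1 <= 0:
        lrt = 0.0
    else:
        lrt = max(n * np.log(rss0 / rss1), 0.0)
    # Gaussian logliks of the e^2 regression, for reporting
    ll0 = -0.5 * n * (np.log(2.0 * np.pi * max(rss0, 1e-300) / n) + 1.0)
    ll1 = ll0 + lrt / 2.0
    p = float(stats.chi2.sf(lrt, 2))
    return HetTestResult(
        method="ols",
        tau=VarParams(*map(float, coef), psd_constrained=False),
        loglik_null=float(ll0),
        loglik_alt=float(ll1),
        lrt=float(lrt),
        df_rule="chisq_2",
        p_het=max(p, np.nextafter(0.0, 1.0)),
        r2_het=pseudo_r2(lrt, n),
        converged=True,
        n_iter=0,
    )


def fit_chisq_regression(
    resid: ResidualSet, g=None, start: Optional[VarParams] = None
) -> HetTestResult:
    """Chi-square regression e^2 = v(G)*chi2_1: unconstrained ML over tau.

    Newton-Raphson with step-halving from the Breusch-Pagan OLS start
    (inflating tau1 if the start is infeasible); LRT against
    :func:`fit_null_variance`, referred to chi2 with 2 df.
    """
    _check_testable(resid)
    e, g = _resid_arrays(resid, g)
    if start is None:
        start = fit_ols_squared(resid, g).tau
    e2 = e * e
    n = e2.size
    _, ll0 = fit_null_variance(resid)
    theta0 = _repair_start(start, g, float(np.var(e)))
    theta, ll1, converged, n_iter = _fit_unconstrained(e2, g, theta0)
    lrt = max(2.0 * (ll1 - ll0), 0.0)
    p = float(stats.chi2.sf(lrt, 2))
    return HetTestResult(
        method="chi2",
        tau=VarParams(*map(float, theta), psd_constrained=False),
        loglik_null=ll0,
        loglik_alt=float(ll1),
        lrt=float(lrt),
        df_rule="chisq_2",
        p_het=max(p, np.nextafter(0.0, 1.0)),
        r2_het=pseudo_r2(lrt, n),
        converged=converged,
        n_iter=n_iter,
    )


def fit_variance_component(
    resid: ResidualSet, g=None, start: Optional[VarParams] = None
) -> HetTestResult:
    """Variance-component model: ML of the same likelihood under the PSD constraint.

    If the unconstrained optimum is positive semidefinite the constraint is
    inactive and the fit equals :func:`fit_chisq_regression`; otherwise the
    optimum lies on the boundary of the PSD cone, parameterized rank-1 as
    tau = (a^2, a*b, b^2), i.e. v(g) = (a + b*g)^2, and is found by a
    2-parameter Newton ascent. The LRT is referred to the 0.5:0.5 mixture
    of chi2 with 1 and 2 df.
    """
    _check_testable(resid)
    e, g = _resid_arrays(resid, g)
    e2 = e * e
    n = e2.size
    tau1_null, ll0 = fit_null_variance(resid)
    if start is None:
        start = fit_ols_squared(resid, g).tau
    theta0 = _repair_start(start, g, float(np.var(e)))
    theta_u, ll_u, conv_u, it_u = _fit_unconstrained(e2, g, theta0)
    cand_u = VarParams(*map(float, theta_u), psd_constrained=True)
    if cand_u.is_psd():
        tau_hat, ll1, converged, n_iter = cand_u, ll_u, conv_u, it_u
    else:
        best = (None, -np.inf, False, 0)
        for ab0 in _rank1_starts(theta_u, tau1_null, g):
            ab, ll_b, conv_b, it_b = _fit_rank1(e2, g, ab0)
            if ll_b > best[1]:
                best = (ab, ll_b, conv_b, it_b)
        ab, ll1, converged, n_iter = best
        n_iter += it_u
        tau_hat = VarParams(
            float(ab[0] ** 2), float(ab[0] * ab[1]), float(ab[1] ** 2),
            psd_constrained=True,
        )
        ll1 = max(ll1, ll0)  # null (b=0) is on the boundary; never fall below
    lrt = max(2.0 * (ll1 - ll0), 0.0)
    return HetTestResult(
        method="vc",
        tau=tau_hat,
        loglik_null=ll0,
        loglik_alt=float(ll1),
        lrt=float(lrt),
        df_rule="mixture_1_2",
        p_het=mixture_pvalue(lrt),
        r2_het=pseudo_r2(lrt, n),
        converged=converged,
        n_iter=n_iter,
    )


def fit_lmm(
    y: np.ndarray, X: np.ndarray, g: np.ndarray
) -> tuple[np.ndarray, HetTestResult]:
    """Joint ML of the linear mixed model with genotype-dependent variance.

    y = X*beta + betaG*g + gamma1 + gamma2*g with var(y_i) = v(g_i). For a
    given tau the fixed effects are the weighted-least-squares solution with
    weights 1/v(g_i) (the profiled likelihood); tau is updated by
    Newton-Raphson with step-halving, under the PSD constraint with the
    mixture null, as in :func:`fit_variance_component`.

    Returns (fixed-effect estimates for [X, g] at the optimum, result).
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    main, resid0 = fit_mean_model(y, X, g)
    _check_testable(resid0)
    A = np.column_stack([np.atleast_2d(np.asarray(X, dtype=float)), g])
    n = y.size
    tau1_null = main.rss_full / n
    ll0 = -0.5 * n * (np.log(2.0 * np.pi * tau1_null) + 1.0)

    state: dict = {}

    def _wls(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        sw = 1.0 / np.sqrt(v)
        beta, _, _, _ = np.linalg.lstsq(A * sw[:, None], y * sw, rcond=None)
        return beta, y - A @ beta

    def make_profiled(vfun: Callable[[np.ndarray], np.ndarray]):
        def loglik(theta: np.ndarray) -> float:
            v = vfun(theta)
            beta, r = _wls(v)
            state["beta"], state["r"] = beta, r
            return _ll_normal(r * r, v)

        return loglik

    U = _vdesign(g)

    def vfun_full(theta: np.ndarray) -> np.ndarray:
        return U @ theta

    def grad_hess_full(theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        # envelope gradient: d beta / d tau terms vanish at the WLS optimum
        v = U @ theta
        _, r = _wls(v)
        e2 = r * r
        rr = e2 / v
        grad = U.T @ (0.5 * (rr - 1.0) / v)
        h = (0.5 - rr) / (v * v)
        hess = (U * h[:, None]).T @ U
        return grad, hess

    def feasible_full(theta: np.ndarray) -> bool:
        return bool(np.min(U @ theta) > 0)

    # start: variance-law OLS on the OLS residuals
    try:
        start = fit_ols_squared(resid0).tau
    except CollinearGenotypeError:
        raise
    theta0 = _repair_start(start, g, float(np.var(resid0.residuals)))
    theta_u, ll_u, conv_u, it_u = _newton_ascent(
        theta0, make_profiled(vfun_full), grad_hess_full, feasible_full
    )
    cand_u = VarParams(*map(float, theta_u), psd_constrained=True)
    if cand_u.is_psd():
        tau_hat, ll1, converged, n_iter = cand_u, ll_u, conv_u, it_u
        make_profiled(vfun_full)(theta_u)  # refresh state at the optimum
    else:
        M = np.column_stack([np.ones_like(g), g])

        def vfun_r1(ab: np.ndarray) -> np.ndarray:
            w = M @ ab
            return w * w

        def grad_hess_r1(ab: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
            w = M @ ab
            _, r = _wls(w * w)
            e2 = r * r
            grad = M.T @ (e2 / w**3 - 1.0 / w)
            h = 1.0 / w**2 - 3.0 * e2 / w**4
            hess = (M * h[:, None]).T @ M
            return grad, hess

        def feasible_r1(ab: np.ndarray) -> bool:
            return bool(np.min(M @ ab) > 0)

        best = (None, -np.inf, False, 0)
        for ab0 in _rank1_starts(theta_u, tau1_null, g):
            ab, ll_b, conv_b, it_b = _newton_ascent(
                ab0, make_profiled(vfun_r1), grad_hess_r1, feasible_r1
            )
            if ll_b > best[1]:
                best = (ab, ll_b, conv_b, it_b)
        ab, ll1, converged, n_iter = best
        n_iter += it_u
        make_profiled(vfun_r1)(ab)
        tau_hat = VarParams(
            float(ab[0] ** 2), float(ab[0] * ab[1]), float(ab[1] ** 2),
            psd_constrained=True,
        )
        ll1 = max(ll1, ll0)
    lrt = max(2.0 * (ll1 - ll0), 0.0)
    result = HetTestResult(
        method="lmm",
        tau=tau_hat,
        loglik_null=float(ll0),
        loglik_alt=float(ll1),
        lrt=float(lrt),
        df_rule="mixture_1_2",
        p_het=mixture_pvalue(lrt),
        r2_het=pseudo_r2(lrt, n),
        converged=converged,
        n_iter=n_iter,
    )
    return np.asarray(state["beta"], dtype=float), result


# ---------------------------------------------------------------------------
# reference distributions, effect size, nonparametric comparison


def mixture_pvalue(q: float) -> float:
    """Boundary null: 0.5*S_chi2(1 df)(q) + 0.5*S_chi2(2 df)(q).

    Used for the vc/lmm LRT, whose null hypothesis places the variance
    parameters on the boundary of the PSD cone.
    """
    if q < 0:
        raise ValueError("LRT statistic must be nonnegative")
    p = 0.5 * stats.chi2.sf(q, 1) + 0.5 * stats.chi2.sf(q, 2)
    return float(max(p, np.nextafter(0.0, 1.0)))


def pseudo_r2(lrt: float, n: int) -> float:
    """Likelihood-ratio-based pseudo-R^2: 1 - exp(-LRT/n) (Cox-Snell/Magee)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if lrt < 0:
        raise ValueError("LRT must be nonnegative")
    return float(-np.expm1(-lrt / n))


def levene_bf(resid: ResidualSet, hard_calls: np.ndarray) -> HetTestResult:
    """Brown-Forsythe (median-centred Levene) test across genotype groups.

    z_ij = |e_ij - median_j|; one-way ANOVA F on z with (k-1, N-k) df.
    Groups with fewer than 2 members are dropped; fewer than 2 usable
    groups is an error.
    """
    _check_testable(resid)
    e = np.asarray(resid.residuals, dtype=float)
    hc = np.asarray(hard_calls)
    if e.shape != hc.shape:
        raise ValueError("residuals and hard_calls must be aligned")
    groups = []
    for value in np.unique(hc):
        if value < 0:  # missing-call sentinel
            continue
        members = e[hc == value]
        if members.size >= 2:
            groups.append(members)
    k = len(groups)
    if k < 2:
        raise GroupingError("fewer than 2 genotype groups with >= 2 members")
    z = [np.abs(grp - np.median(grp)) for grp in groups]
    N = sum(zi.size for zi in z)
    grand = sum(zi.sum() for zi in z) / N
    ssb = sum(zi.size * (zi.mean() - grand) ** 2 for zi in z)
    ssw = sum(((zi - zi.mean()) ** 2).sum() for zi in z)
    df1, df2 = k - 1, N - k
    if ssw <= 0:
        fstat = 0.0 if ssb <= 0 else np.inf
    else:
        fstat = (ssb / df1) / (ssw / df2)
    p = float(stats.f.sf(fstat, df1, df2)) if np.isfinite(fstat) else 0.0
    return HetTestResult(
        method="levene",
        tau=None,
        loglik_null=np.nan,
        loglik_alt=np.nan,
        lrt=float(fstat),
        df_rule="f_levene",
        p_het=max(p, np.nextafter(0.0, 1.0)),
        r2_het=np.nan,
        converged=True,
        n_iter=0,
    )
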