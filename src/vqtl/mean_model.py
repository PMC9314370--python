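"""Mean model: covariates + additive SNP effect, fitted by OLS.

The variance tests in :mod:`vqtl.het_tests` operate on the residuals of the
trait after removing covariate effects and the additive genetic effect.
This module produces those residuals together with the standard-GWAS
main-effect statistics (beta, SE, p, partial R^2) for the SNP.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import (
    DegenerateResidualsError,
    MonomorphicVariantError,
    RankDeficiencyError,
)

__all__ = ["MainEffectResult", "ResidualSet", "fit_mean_model", "partial_r2"]

# Above this sample size the Wald p-value uses the normal reference; below,
# the exact t reference under Gaussian errors.
NORMAL_REFERENCE_N = 5000


@dataclass
class MainEffectResult:
    """Standard-GWAS additive-effect statistics for one variant.

    ``r2_main`` is the partial R^2 of the SNP after the covariates:
    (rss_cov - rss_full) / rss_cov.
    """

    beta_g: float
    se: float
    p_main: float
    r2_main: float
    rss_cov: float
    rss_full: float
    n: int


@dataclass
class ResidualSet:
    """Residuals of the full mean model, aligned with the genotype vector.

    ``degenerate`` flags an (almost) exact fit — zero residual variance —
    which makes every variance test undefined; downstream fitters raise
    :class:`~vqtl.exceptions.DegenerateResidualsError` on such input.
    """

    residuals: np.ndarray
    n: int
    genotype: np.ndarray
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.residuals = np.asarray(self.residuals, dtype=float)
        self.genotype = np.asarray(self.genotype, dtype=float)
        if self.residuals.shape != self.genotype.shape:
            raise ValueError("residuals and genotype must be aligned")


def _ols(design: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, int]:
    """Least squares fit returning (coef, rss, rank)."""
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return coef, float(resid @ resid), int(rank)


def fit_mean_model(
    y: np.ndarray,
    X: np.ndarray,
    g: np.ndarray,
) -> tuple[MainEffectResult, ResidualSet]:
    """OLS of the trait on covariates (``X``, including intercept) and dosage ``g``.

    Returns the main-effect statistics for ``g`` and the residuals of the
    full fit. Raises :class:`MonomorphicVariantError` for a constant
    genotype and :class:`RankDeficiencyError` for a singular design.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    g = np.asarray(g, dtype=float)
    if X.shape[0] != y.shape[0] or g.shape[0] != y.shape[0]:
        raise ValueError("y, X and g must have the same number of rows")
    if np.ptp(g) == 0:
        raise MonomorphicVariantError("genotype vector is constant")

    n = y.shape[0]
    design = np.column_stack([X, g])
    p = design.shape[1]
    if n <= X.shape[1] + 1:
        raise ValueError(f"need n > n_covariates + 1 (n={n})")

    coef, rss_full, rank = _ols(design, y)
    if rank < p:
        raise RankDeficiencyError("mean-model design is rank deficient")
    _, rss_cov, rank_cov = _ols(X, y)
    if rank_cov < X.shape[1]:
        raise RankDeficiencyError("covariate design is rank deficient")
    if rss_cov <= 0:
        raise DegenerateResidualsError("trait is an exact function of covariates")

    resid = y - design @ coef
    degenerate = rss_full <= 1e-12 * rss_cov

    dof = n - p
    sigma2 = rss_full / dof
    xtx_inv = np.linalg.inv(design.T @ design)
    se = float(np.sqrt(max(sigma2 * xtx_inv[-1, -1], 0.0)))
    beta_g = float(coef[-1])
    if se == 0.0:
        p_main = 0.0 if beta_g != 0 else 1.0
    else:
        z = abs(beta_g) / se
        if n >= NORMAL_REFERENCE_N:
            p_main = float(2.0 * stats.norm.sf(z))
        else:
            p_main = float(2.0 * stats.t.sf(z, dof))
    p_main = max(p_main, np.nextafter(0.0, 1.0))

    result = MainEffectResult(
        beta_g=beta_g,
        se=se,
        p_main=p_main,
        r2_main=(rss_cov - rss_full) / rss_cov,
        rss_cov=rss_cov,
        rss_full=rss_full,
        n=n,
    )
    residual_set = ResidualSet(residuals=resid, n=n, genotype=g, degenerate=degenerate)
    return result, residual_set


def partial_r2(rss_cov: float, rss_full: float) -> float:
    """Partial R^2 of the SNP term: (rss_cov - rss_full) / rss_cov.

    Requires 0 < rss_full <= rss_cov.
    """
    if not rss_full > 0:
        raise ValueError("rss_full must be positive")
    if rss_full > rss_cov * (1 + 1e-12):
        raise ValueError("rss_full exceeds rss_cov")
    return max((rss_cov - rss_full) / rss_cov, 0.0)
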