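"""Synthetic cohorts and the two simulation studies: null calibration and power.

The generator emulates a biobank-scale systolic-blood-pressure cohort:
HWE genotypes (allele counts Binomial(2, maf)), covariates (sex, age in
40-69, BMI, 10 principal components), and a trait built from the fitted
null SBP model

    SBP = 86.5 + 5.65*sex + 0.00827*age^2 + 0.909*BMI
          + 0.0647*PC4 + 0.0349*PC9 + sum_i beta_i*SNP_i + eps,

with eps ~ N(0, 18.44^2), plus (for power studies) one focal SNP whose
per-individual effect is random, b_j ~ N(-0.475, sigma^2) i.i.d. across
individuals. A per-individual random slope with variance sigma^2 induces
exactly tau3 = sigma^2, tau2 = 0 in the variance law, so the vQTL tests can
be checked both for size (sigma^2 = 0) and power.

Randomness is fully deterministic under a master seed: every stream
(covariates, background genotypes, per-replicate noise, ...) is derived
from the master seed and a fixed integer tag via ``numpy.random.SeedSequence``,
so each replicate is reproducible in isolation. Power replicates reuse the
same noise stream at every sigma^2 level (common random numbers), which
sharpens comparisons across levels and across tests.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import het_tests
from .data_io import TraitVector
from .mean_model import ResidualSet, fit_mean_model

__all__ = [
    "SimulationSpec",
    "PowerResult",
    "CalibrationResult",
    "default_background_snps",
    "simulate_genotypes",
    "simulate_covariates",
    "simulate_trait",
    "simulate_random_slope_trait",
    "null_calibration",
    "estimate_power",
]

COVARIATE_NAMES = ["sex", "age", "age2", "bmi"] + [f"pc{i}" for i in range(1, 11)]

# stream tags for seed derivation
_TAG_COVARIATES = 1
_TAG_BACKGROUND = 2
_TAG_NOISE = 3
_TAG_TEST_SNPS = 4
_TAG_FOCAL = 5
_TAG_REPLICATE = 6


def _rng(seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, tags)]))


@dataclass
class SimulationSpec:
    """Study conditions for the SBP-style simulations.

    Defaults are desk scale (n = 10,000, 300 replicates, alpha = 0.05);
    :meth:`biobank_scale` returns the full biobank configuration
    (n = 396,387, 1000 replicates, genome-wide alpha = 5e-8).
    """

    n: int = 10_000
    intercept: float = 86.5
    beta_sex: float = 5.65
    beta_age2: float = 0.00827
    beta_bmi: float = 0.909
    beta_pcs: tuple = (0, 0, 0, 0.0647, 0, 0, 0, 0, 0.0349, 0)
    snp_effects: Optional[list[tuple[float, float]]] = None
    focal_maf: float = 0.3
    focal_mu: float = -0.475
    focal_sigma2: float = 0.0
    error_sd: float = 18.44
    replicates: int = 300
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.focal_maf <= 0.5:
            raise ValueError("focal_maf must be in (0, 0.5]")
        if self.focal_sigma2 < 0 or self.error_sd <= 0 or self.replicates < 1:
            raise ValueError("invalid simulation parameters")

    @classmethod
    def biobank_scale(cls, **overrides) -> "SimulationSpec":
        base = dict(n=396_387, replicates=1000, alpha=5e-8)
        base.update(overrides)
        return cls(**base)

    def background(self) -> list[tuple[float, float]]:
        if self.snp_effects is not None:
            return list(self.snp_effects)
        return default_background_snps(seed=self.seed)


@dataclass
class PowerResult:
    """Empirical power at one heteroscedasticity level for one test."""

    sigma2: float
    method: str
    power: float
    mc_se: float
    replicates: int


@dataclass
class CalibrationResult:
    """Null-calibration summary: p-values, rejection rates, QQ points."""

    method: str
    pvalues: np.ndarray
    rejection: dict  # alpha -> (rate, binomial SE)
    qq: np.ndarray
    n_snps: int


def default_background_snps(
    n_snps: int = 54, seed: int = 0
) -> list[tuple[float, float]]:
    """(maf, beta) pairs for the background polygenic SNPs.

    54 pairs with MAF ~ U(0.05, 0.5) and effects ~ N(0, 0.3^2) mm Hg —
    structural stand-ins for published SBP association panels, at typical
    BP-GWAS effect sizes. Deterministic given the seed.
    """
    rng = _rng(seed, _TAG_BACKGROUND, 999)
    mafs = rng.uniform(0.05, 0.5, size=n_snps)
    betas = rng.normal(0.0, 0.3, size=n_snps)
    return list(zip(mafs.tolist(), betas.tolist()))


def simulate_genotypes(n: int, maf: float, seed) -> np.ndarray:
    """HWE hard-call genotypes: coded-allele counts ~ Binomial(2, maf)."""
    if not 0 < maf <= 0.5:
        raise ValueError("maf must be in (0, 0.5]")
    rng = seed if isinstance(seed, np.random.Generator) else _rng(seed, _TAG_FOCAL)
    return rng.binomial(2, maf, size=n).astype(np.int8)


def simulate_covariates(n: int, seed) -> pd.DataFrame:
    """Covariate table: sex ~ Bern(0.46), age ~ U(40, 69), BMI ~ N(27, 4.8^2)
    truncated positive, 10 standard-normal PCs; age2 = age^2."""
    rng = seed if isinstance(seed, np.random.Generator) else _rng(seed, _TAG_COVARIATES)
    sex = rng.binomial(1, 0.46, size=n).astype(float)
    age = rng.uniform(40.0, 69.0, size=n)
    bmi = rng.normal(27.0, 4.8, size=n)
    while np.any(bmi <= 0):  # truncation; essentially never triggers
        bad = bmi <= 0
        bmi[bad] = rng.normal(27.0, 4.8, size=int(bad.sum()))
    pcs = rng.standard_normal((n, 10))
    data = {"sex": sex, "age": age, "age2": age * age, "bmi": bmi}
    for i in range(10):
        data[f"pc{i + 1}"] = pcs[:, i]
    return pd.DataFrame(data)


def _fixed_part(
    spec: SimulationSpec,
    covariates: pd.DataFrame,
    background_G: Optional[np.ndarray],
    background_beta: Optional[np.ndarray],
) -> np.ndarray:
    y = (
        spec.intercept
        + spec.beta_sex * covariates["sex"].to_numpy()
        + spec.beta_age2 * covariates["age2"].to_numpy()
        + spec.beta_bmi * covariates["bmi"].to_numpy()
    )
    for i, b in enumerate(spec.beta_pcs):
        if b:
            y = y + b * covariates[f"pc{i + 1}"].to_numpy()
    if background_G is not None:
        y = y + background_G @ np.asarray(background_beta, dtype=float)
    return y


def simulate_trait(
    spec: SimulationSpec,
    covariates: pd.DataFrame,
    g_focal: Optional[np.ndarray] = None,
    background: Optional[tuple[np.ndarray, np.ndarray]] = None,
    seed=None,
    sigma2: Optional[float] = None,
) -> TraitVector:
    """One simulated SBP trait.

    The focal-SNP effect is b_j = mu + sigma*z_j with z_j standard normal
    drawn per individual; the null generator (sigma^2 = 0) consumes the
    same draws, so a run at sigma^2 = 0 reproduces the null trait exactly
    under the same seed.
    """
    n = len(covariates)
    rng = seed if isinstance(seed, np.random.Generator) else _rng(
        spec.seed if seed is None else seed, _TAG_NOISE
    )
    sigma2 = spec.focal_sigma2 if sigma2 is None else float(sigma2)
    y = _fixed_part(spec, covariates, *(background or (None, None)))
    z = rng.standard_normal(n)
    eps = rng.standard_normal(n) * spec.error_sd
    if g_focal is not None:
        g_focal = np.asarray(g_focal, dtype=float)
        if g_focal.shape[0] != n:
            raise ValueError("focal genotype not aligned with covariates")
        b = spec.focal_mu + np.sqrt(sigma2) * z
        y = y + b * g_focal
    return TraitVector(y + eps, "SBP", transform_log=False, n=n)


def simulate_random_slope_trait(
    n: int,
    maf: float,
    mu: float,
    sigma2: float,
    error_sd: float = 1.0,
    seed=0,
) -> tuple[np.ndarray, np.ndarray]:
    """Minimal random-slope trait y = (mu + sigma*z)*g + eps.

    Strips the cohort structure away: after regressing y on (1, g) the
    residual variance law is exactly tau1 = error_sd^2, tau2 = 0,
    tau3 = sigma2 — the cleanest setting for parameter-recovery checks.
    Returns (y, g).
    """
    rng = seed if isinstance(seed, np.random.Generator) else _rng(seed, _TAG_NOISE)
    g = rng.binomial(2, maf, size=n).astype(float)
    z = rng.standard_normal(n)
    eps = rng.standard_normal(n) * error_sd
    y = (mu + np.sqrt(sigma2) * z) * g + eps
    return y, g


def _design(covariates: pd.DataFrame) -> np.ndarray:
    return np.column_stack(
        [np.ones(len(covariates))]
        + [covariates[c].to_numpy(dtype=float) for c in COVARIATE_NAMES]
    )


def _residual_test(method: str, resid: ResidualSet, y, X, g) -> float:
    if method == "ols":
        return het_tests.fit_ols_squared(resid).p_het
    if method == "chi2":
        return het_tests.fit_chisq_regression(resid).p_het
    if method == "vc":
        return het_tests.fit_variance_component(resid).p_het
    if method == "lmm":
        return het_tests.fit_lmm(y, X, g)[1].p_het
    raise ValueError(f"unknown method {method!r}")


def _build_cohort(spec: SimulationSpec):
    covariates = simulate_covariates(spec.n, _rng(spec.seed, _TAG_COVARIATES))
    bg = spec.background()
    rng_bg = _rng(spec.seed, _TAG_BACKGROUND)
    G_bg = np.column_stack(
        [simulate_genotypes(spec.n, maf, rng_bg) for maf, _ in bg]
    ).astype(float)
    beta_bg = np.array([b for _, b in bg])
    return covariates, G_bg, beta_bg


def null_calibration(
    spec: SimulationSpec,
    method: str = "vc",
    n_snps: int = 2000,
    alphas: Sequence[float] = (0.05,),
    maf_range: tuple[float, float] = (0.05, 0.5),
    n_traits: int = 1,
) -> CalibrationResult:
    """Size of one test under the null: constant-effect trait(s), many SNPs.

    Simulates a null trait (all SNP effects constant), then tests ``n_snps``
    independent synthetic SNPs that play no role in the trait; their
    p-values should be uniform. With ``n_traits`` > 1 the SNPs are split
    across that many independently drawn traits: tests sharing one trait
    realization are positively correlated (through its residual kurtosis),
    which at desk-scale n inflates the variance of the rejection rate
    beyond binomial; batching restores the independence a binomial error
    band assumes.
    """
    from .scan import qq_points

    covariates, G_bg, beta_bg = _build_cohort(spec)
    X = _design(covariates)
    rng_snp = _rng(spec.seed, _TAG_TEST_SNPS)
    batches = np.array_split(np.arange(n_snps), n_traits)
    pvals = np.empty(n_snps)
    for t, batch in enumerate(batches):
        y = simulate_trait(
            spec,
            covariates,
            g_focal=None,
            background=(G_bg, beta_bg),
            seed=_rng(spec.seed, _TAG_NOISE, t),
        ).values
        for j in batch:
            # redraw until all three genotype classes are observed: the
            # quadratic variance law needs them, and a scan would skip the
            # variant otherwise
            while True:
                maf = rng_snp.uniform(*maf_range)
                g = simulate_genotypes(spec.n, maf, rng_snp).astype(float)
                if np.unique(g).size >= 3:
                    break
            _, resid = fit_mean_model(y, X, g)
            pvals[j] = _residual_test(method, resid, y, X, g)
    rejection = {
        a: (
            float(np.mean(pvals < a)),
            float(np.sqrt(a * (1 - a) / n_snps)),
        )
        for a in alphas
    }
    return CalibrationResult(
        method=method,
        pvalues=pvals,
        rejection=rejection,
        qq=qq_points(pvals),
        n_snps=n_snps,
    )


def estimate_power(
    spec: SimulationSpec,
    methods: Sequence[str] | str = ("vc",),
    sigma2_grid: Sequence[float] = (1.0, 2.0, 3.0, 4.0, 5.0),
) -> list[PowerResult]:
    """Empirical power of the tests over a grid of heteroscedasticity levels.

    Cohort (covariates, background and focal genotypes) is built once;
    each replicate redraws the per-individual random slopes and the error,
    and the same replicate stream is reused at every sigma^2 level (common
    random numbers). Power is the fraction of replicates with
    p < spec.alpha.
    """
    if isinstance(methods, str):
        methods = [methods]
    if not sigma2_grid:
        raise ValueError("sigma2_grid must be non-empty")
    covariates, G_bg, beta_bg = _build_cohort(spec)
    g = simulate_genotypes(
        spec.n, spec.focal_maf, _rng(spec.seed, _TAG_FOCAL)
    ).astype(float)
    X = _design(covariates)
    A = np.column_stack([X, g])
    Q, _ = np.linalg.qr(A)
    fixed = _fixed_part(spec, covariates, G_bg, beta_bg)
    sig = {(m, s2): 0 for m in methods for s2 in sigma2_grid}
    for r in range(spec.replicates):
        rng = _rng(spec.seed, _TAG_REPLICATE, r)
        z = rng.standard_normal(spec.n)
        eps = rng.standard_normal(spec.n) * spec.error_sd
        for s2 in sigma2_grid:
            b = spec.focal_mu + np.sqrt(s2) * z
            y = fixed + b * g + eps
            e = y - Q @ (Q.T @ y)
            resid = ResidualSet(e, spec.n, g)
            for m in methods:
                p = _residual_test(m, resid, y, X, g)
                if p < spec.alpha:
                    sig[(m, s2)] += 1
    out = []
    for m in methods:
        for s2 in sigma2_grid:
            power = sig[(m, s2)] / spec.replicates
            out.append(
                PowerResult(
                    sigma2=float(s2),
                    method=m,
                    power=power,
                    mc_se=float(np.sqrt(power * (1 - power) / spec.replicates)),
                    replicates=spec.replicates,
                )
            )
    return out
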