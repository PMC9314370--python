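"""Genome-wide vQTL scan driver.

For each variant passing the filters: complete-case alignment of trait,
covariates and dosage; OLS mean model (standard-GWAS main effect);
residual-based heteroscedasticity test(s); one output record per variant
per method. The scan is deterministic given inputs and configuration, and
records are emitted in input variant order.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import het_tests
from .data_io import (
    BP_TRAITS,
    GenotypeBlock,
    PhenotypeTable,
    TraitVector,
    apply_sample_filters,
    apply_variant_filters,
    hard_call,
    prepare_bp_traits,
    write_scan_results,
)
from .exceptions import DataError, VqtlError

__all__ = ["ScanConfig", "run_scan", "qq_points", "METHODS"]

METHODS = ("lmm", "vc", "ols", "chi2", "levene")

logger = logging.getLogger("vqtl.scan")


@dataclass
class ScanConfig:
    """Configuration of one scan run."""

    method: str = "vc"
    maf_min: float = 0.01
    info_min: Optional[float] = 0.9
    alpha_gw: float = 5e-8
    trait: str = "SBP"
    covariates: Sequence[str] = ("sex", "age", "age2", "bmi")
    out: Optional[str] = None
    threads: int = 1

    def __post_init__(self) -> None:
        if self.method not in METHODS + ("all",):
            raise ValueError(f"method must be one of {METHODS + ('all',)}")
        if not 0.0 < self.alpha_gw < 1.0:
            raise ValueError("alpha_gw must be in (0, 1)")

    @property
    def method_list(self) -> list[str]:
        return list(METHODS) if self.method == "all" else [self.method]


def _run_one_method(method, resid, y, X, g):
    if method == "ols":
        return het_tests.fit_ols_squared(resid)
    if method == "chi2":
        return het_tests.fit_chisq_regression(resid)
    if method == "vc":
        return het_tests.fit_variance_component(resid)
    if method == "lmm":
        _, res = het_tests.fit_lmm(y, X, g)
        return res
    if method == "levene":
        return het_tests.levene_bf(resid, hard_call(g))
    raise ValueError(method)


def run_scan(
    geno: GenotypeBlock,
    pheno: PhenotypeTable,
    config: ScanConfig,
    trait_vector: Optional[TraitVector] = None,
) -> list[dict]:
    """Run the scan and return one record dict per variant per method.

    ``trait_vector`` overrides the built-in trait preparation for generic
    (non-blood-pressure) traits: it must be row-aligned with ``pheno``.
    When ``config.out`` is set, results are also written as TSV.
    """
    if trait_vector is None:
        if config.trait.upper() in BP_TRAITS:
            trait_vector = prepare_bp_traits(pheno, config.trait)
        elif config.trait in pheno.df.columns:
            vals = pheno.df[config.trait].to_numpy(dtype=float)
            trait_vector = TraitVector(vals, config.trait, False, len(vals))
        else:
            raise DataError(f"trait {config.trait!r} not found in phenotype table")

    retained = apply_sample_filters(pheno, [trait_vector])
    kept_ids = [pheno.sample_ids[i] for i in retained]
    geno_index = {s: i for i, s in enumerate(geno.sample_ids)}
    pairs = [(row, geno_index[s]) for row, s in zip(retained, kept_ids) if s in geno_index]
    if not pairs:
        raise DataError("no overlapping samples between genotypes and phenotypes")
    ph_idx = np.array([p[0] for p in pairs], dtype=int)
    gt_idx = np.array([p[1] for p in pairs], dtype=int)

    y_all = trait_vector.values[ph_idx]
    X_all = np.column_stack(
        [np.ones(len(ph_idx)), pheno.covariate_matrix()[ph_idx]]
    )

    block = apply_variant_filters(geno, config.maf_min, config.info_min)
    logger.info(
        "scan: %d samples, %d/%d variants pass filters, methods=%s",
        len(ph_idx), block.n_variants, geno.n_variants, config.method_list,
    )

    records: list[dict] = []
    for j in range(block.n_variants):
        vid = block.variant_ids[j]
        d = block.dosages[gt_idx, j]
        cc = np.isfinite(d)
        g = d[cc]
        if g.size < X_all.shape[1] + 2 or np.ptp(g) == 0:
            logger.info("skip %s: monomorphic or too few complete cases", vid)
            continue
        y = y_all[cc]
        X = X_all[cc]
        try:
            main, resid = het_tests.fit_mean_model(y, X, g)
        except VqtlError as err:
            logger.info("skip %s: %s", vid, err)
            continue
        caf_cc = float(np.mean(g) / 2.0)
        base = {
            "variant_id": vid,
            "chrom": str(block.chrom[j]),
            "pos": int(block.pos[j]),
            "NCA": str(block.noncoded_allele[j]),
            "CA": str(block.coded_allele[j]),
            "CAF": caf_cc,
            "n": int(g.size),
            "beta_main": main.beta_g,
            "se_main": main.se,
            "p_main": main.p_main,
            "r2_main": main.r2_main,
        }
        for method in config.method_list:
            try:
                res = _run_one_method(method, resid, y, X, g)
            except VqtlError as err:
                logger.info("skip %s [%s]: %s", vid, method, err)
                continue
            tau = res.tau
            records.append(
                base
                | {
                    "tau1": np.nan if tau is None else tau.tau1,
                    "tau2": np.nan if tau is None else tau.tau2,
                    "tau3": np.nan if tau is None else tau.tau3,
                    "lrt_het": res.lrt,
                    "p_het": res.p_het,
                    "r2_het": res.r2_het,
                    "method": method,
                    "converged": res.converged,
                    "n_iter": res.n_iter,
                }
            )
    if config.out is not None:
        write_scan_results(records, config.out)
    return records


def significant(records: Sequence[dict], alpha: float) -> list[dict]:
    """Records with p_het strictly below ``alpha``."""
    return [r for r in records if r["p_het"] < alpha]


def qq_points(pvals: Sequence[float]) -> np.ndarray:
    """(expected, observed) -log10 pairs for a QQ plot.

    The i-th smallest p-value is paired with the uniform-order-statistic
    midpoint (i - 0.5)/m. Returns an (m, 2) array, columns (expected,
    observed), ordered by ascending p.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    observed = -np.log10(np.sort(p))
    expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)
    return np.column_stack([expected, observed])
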