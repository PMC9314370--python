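"""Genotype and phenotype I/O, blood-pressure trait preparation, filters.

Genotypes come either from VCF 4.x (the per-sample ``DS`` dosage field is
preferred, with the ``GT`` hard call as fallback) or from a plain TSV dosage
matrix (one row per variant; columns 1-5 are variant_id, chrom, pos,
noncoded allele, coded allele, optionally followed by an ``info`` column,
then one dosage column per sample). The coded allele is the allele whose
copies the dosage counts (first ALT for VCF).

Phenotypes are a TSV with a ``sample_id`` key column, raw blood-pressure
measurements, a ``medication`` flag and covariates. Blood-pressure traits
are prepared the standard way for hypertension genetics: measurements are
averaged, +15 mm Hg (SBP) or +10 mm Hg (DBP) is added for medicated
participants to undo treatment, pulse pressure is the adjusted difference
SBP - DBP and is log-transformed because of its long right tail.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import DataError, FilterError

__all__ = [
    "GenotypeBlock",
    "PhenotypeTable",
    "TraitVector",
    "read_genotype_matrix",
    "hard_call",
    "prepare_bp_traits",
    "apply_sample_filters",
    "apply_variant_filters",
    "write_scan_results",
    "read_scan_results",
    "SCAN_COLUMNS",
]

BP_TRAITS = ("SBP", "DBP", "PP")

SCAN_COLUMNS = [
    "variant_id", "chrom", "pos", "NCA", "CA", "CAF", "n",
    "beta_main", "se_main", "p_main", "r2_main",
    "tau1", "tau2", "tau3", "lrt_het", "p_het", "r2_het",
    "method", "converged", "n_iter",
]


@dataclass
class GenotypeBlock:
    """Per-variant dosages with metadata, samples x variants.

    Missing dosages are NaN. ``caf`` is the coded-allele frequency,
    mean(dosage)/2 over non-missing samples. ``info`` is the imputation
    info score when supplied by the source, else None.
    """

    variant_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    noncoded_allele: np.ndarray
    coded_allele: np.ndarray
    dosages: np.ndarray
    sample_ids: list[str]
    caf: np.ndarray = field(default=None)  # type: ignore[assignment]
    info: Optional[np.ndarray] = None
    hard_calls: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DataError("duplicate sample IDs in genotype source")
        self.dosages = np.asarray(self.dosages, dtype=float)
        finite = self.dosages[np.isfinite(self.dosages)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 2 + 1e-9):
            raise DataError("dosages must lie in [0, 2]")
        if self.caf is None:
            self.caf = self.compute_caf()

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def compute_caf(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def subset_variants(self, mask: np.ndarray) -> "GenotypeBlock":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return GenotypeBlock(
            variant_ids=[self.variant_ids[i] for i in idx],
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            noncoded_allele=self.noncoded_allele[idx],
            coded_allele=self.coded_allele[idx],
            dosages=self.dosages[:, idx],
            sample_ids=list(self.sample_ids),
            caf=self.caf[idx],
            info=None if self.info is None else self.info[idx],
            hard_calls=None if self.hard_calls is None else self.hard_calls[:, idx],
        )


@dataclass
class PhenotypeTable:
    """Phenotype/covariate table keyed by ``sample_id``.

    ``covariates`` names the columns entering the mean model (sex, age,
    age2, BMI, principal components, ...). An ``age2`` column is derived
    from ``age`` automatically when absent.
    """

    df: pd.DataFrame
    covariates: list[str]

    def __post_init__(self) -> None:
        if "sample_id" not in self.df.columns:
            raise DataError("phenotype table needs a 'sample_id' column")
        if self.df["sample_id"].duplicated().any():
            raise DataError("duplicate sample IDs in phenotype table")
        if "age2" in self.covariates and "age2" not in self.df.columns:
            if "age" not in self.df.columns:
                raise DataError("age2 requested but no age column")
            self.df = self.df.assign(age2=self.df["age"] ** 2)
        missing = [c for c in self.covariates if c not in self.df.columns]
        if missing:
            raise DataError(f"missing covariate columns: {missing}")

    @property
    def sample_ids(self) -> list[str]:
        return self.df["sample_id"].astype(str).tolist()

    @property
    def n(self) -> int:
        return len(self.df)

    def covariate_matrix(self) -> np.ndarray:
        return self.df[self.covariates].to_numpy(dtype=float)

    @classmethod
    def from_tsv(cls, path, covariates: Sequence[str]) -> "PhenotypeTable":
        df = pd.read_csv(path, sep="\t")
        return cls(df=df, covariates=list(covariates))


@dataclass
class TraitVector:
    """A prepared trait, one value per sample row of the source table."""

    values: np.ndarray
    trait_name: str
    transform_log: bool
    n: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.n = int(self.values.size)


# ---------------------------------------------------------------------------
# genotype reading


def _read_vcf(path: Path) -> GenotypeBlock:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    ids, chroms, poss, ncas, cas, infos, rows = [], [], [], [], [], [], []
    any_info = False
    for var in vcf:
        ds = None
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            d = np.asarray(ds, dtype=float).reshape(len(samples), -1)[:, 0]
            d = d.copy()
            bad = ~np.isfinite(d) | (d < -0.5) | (d > 2.5)
            d[bad] = np.nan
        else:
            gt = np.asarray(var.gt_types, dtype=float)
            gt[gt == 3] = np.nan  # 3 = unknown under gts012
            d = gt
        if not np.any(np.isfinite(d)):
            # record kept; caf is NaN and the variant filter will drop it
            pass
        alt = var.ALT[0] if var.ALT else "."
        score = None
        for key in ("INFO", "R2", "DR2"):
            val = var.INFO.get(key)
            if val is not None:
                score = float(val)
                break
        any_info = any_info or score is not None
        ids.append(var.ID if var.ID else f"{var.CHROM}:{var.POS}")
        chroms.append(str(var.CHROM))
        poss.append(int(var.POS))
        ncas.append(str(var.REF))
        cas.append(alt)
        infos.append(np.nan if score is None else score)
        rows.append(d)
    if not rows:
        raise DataError(f"no variants parsed from {path}")
    return GenotypeBlock(
        variant_ids=ids,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=int),
        noncoded_allele=np.array(ncas, dtype=object),
        coded_allele=np.array(cas, dtype=object),
        dosages=np.column_stack(rows),
        sample_ids=samples,
        info=np.array(infos, dtype=float) if any_info else None,
    )


def _read_tsv(path: Path) -> GenotypeBlock:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 6:
        raise DataError("dosage TSV needs 5 metadata columns plus samples")
    meta_cols = list(df.columns[:5])
    rest = list(df.columns[5:])
    info = None
    if rest and rest[0].lower() == "info":
        info = df[rest[0]].to_numpy(dtype=float)
        rest = rest[1:]
    if not rest:
        raise DataError("dosage TSV has no sample columns")
    dos = df[rest].to_numpy(dtype=float).T  # samples x variants
    return GenotypeBlock(
        variant_ids=df[meta_cols[0]].astype(str).tolist(),
        chrom=df[meta_cols[1]].astype(str).to_numpy(dtype=object),
        pos=df[meta_cols[2]].to_numpy(dtype=int),
        noncoded_allele=df[meta_cols[3]].astype(str).to_numpy(dtype=object),
        coded_allele=df[meta_cols[4]].astype(str).to_numpy(dtype=object),
        dosages=dos,
        sample_ids=[str(s) for s in rest],
        info=info,
    )


def read_genotype_matrix(path, format: Optional[str] = None) -> GenotypeBlock:
    """Read a :class:`GenotypeBlock` from VCF or a TSV dosage matrix.

    ``format`` is "vcf" or "tsv"; when omitted it is inferred from the file
    extension.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    if format is None:
        suffixes = {s.lower() for s in path.suffixes}
        format = "vcf" if ".vcf" in suffixes or ".bcf" in suffixes else "tsv"
    if format == "vcf":
        return _read_vcf(path)
    if format == "tsv":
        return _read_tsv(path)
    raise ValueError(f"unknown genotype format: {format!r}")


def hard_call(x) -> np.ndarray:
    """Most probable hard genotype call in {0, 1, 2}.

    With genotype probabilities (last axis of length 3) returns the argmax,
    ties broken toward the smaller genotype. With dosages returns the
    nearest integer, a half-integer dosage again rounding down. Missing
    dosages (NaN) map to -1.
    """
    arr = np.asarray(x, dtype=float)
    # a length-3 vector in [0,1] summing to ~1 is a probability triple;
    # anything else is dosage
    is_probs = arr.ndim == 2 and arr.shape[-1] == 3
    if arr.ndim == 1 and arr.shape[0] == 3:
        finite = arr[np.isfinite(arr)]
        if finite.size and finite.min() >= 0 and finite.max() <= 1 and abs(
            np.nansum(arr) - 1.0
        ) <= 0.01:
            is_probs = True
    if is_probs:
        probs = np.atleast_2d(arr)
        if np.any(~np.isfinite(probs).any(axis=1)):
            raise DataError("all genotype probabilities missing")
        sums = np.nansum(probs, axis=1)
        if np.any(np.abs(sums - 1.0) > 0.01):
            raise DataError("genotype probabilities must sum to ~1")
        calls = np.nanargmax(probs, axis=1).astype(int)
        return calls if arr.ndim == 2 else int(calls[0])
    d = np.atleast_1d(arr)
    frac = d - np.floor(d)
    calls = np.where(frac == 0.5, np.floor(d), np.floor(d + 0.5))
    calls = np.clip(calls, 0, 2)
    out = np.where(np.isfinite(d), calls, -1).astype(int)
    return out if np.ndim(x) else int(out[0])


# ---------------------------------------------------------------------------
# trait preparation and filters

_MEDICATION_MMHG = {"SBP": 15.0, "DBP": 10.0}


def _measurement_mean(df: pd.DataFrame, prefix: str) -> np.ndarray:
    cols = [c for c in df.columns if c.lower() == prefix or c.lower().startswith(prefix + "_")]
    if not cols:
        raise DataError(f"no {prefix.upper()} measurement columns")
    return df[cols].mean(axis=1, skipna=True).to_numpy(dtype=float)


def _adjusted_bp(table: PhenotypeTable, which: str) -> np.ndarray:
    if "medication" not in table.df.columns:
        raise DataError("phenotype table needs a 'medication' column")
    med = table.df["medication"].to_numpy(dtype=float)
    raw = _measurement_mean(table.df, which.lower())
    return raw + _MEDICATION_MMHG[which] * med


def prepare_bp_traits(table: PhenotypeTable, trait: str) -> TraitVector:
    """Prepare SBP, DBP or PP the way hypertension GWAS do.

    SBP/DBP: mean of available measurements, +15/+10 mm Hg for medicated
    samples. PP: adjusted SBP minus adjusted DBP, then natural log. Values
    stay row-aligned with the table; missing measurements propagate as NaN
    and are removed by :func:`apply_sample_filters`.
    """
    trait = trait.upper()
    if trait not in BP_TRAITS:
        raise ValueError(f"trait must be one of {BP_TRAITS}")
    if trait in ("SBP", "DBP"):
        values = _adjusted_bp(table, trait)
        return TraitVector(values, trait, transform_log=False, n=len(values))
    pp = _adjusted_bp(table, "SBP") - _adjusted_bp(table, "DBP")
    nonpos = np.isfinite(pp) & (pp <= 0)
    if np.any(nonpos):
        raise DataError(
            f"{int(nonpos.sum())} samples have non-positive pulse pressure"
        )
    with np.errstate(invalid="ignore"):
        return TraitVector(np.log(pp), "PP", transform_log=True, n=len(pp))


def apply_sample_filters(
    table: PhenotypeTable,
    traits: Sequence[TraitVector],
    sd_limit: float = 5.0,
) -> np.ndarray:
    """Indices of samples passing missingness and outlier screens.

    Drops samples with any missing trait or covariate value, then samples
    whose trait or BMI lies ``sd_limit`` or more sample SDs from the sample
    mean. Mean and SD are computed once, on the samples passing the
    missingness screen (no iterative re-screening).
    """
    n = table.n
    keep = np.ones(n, dtype=bool)
    cov = table.covariate_matrix()
    keep &= np.isfinite(cov).all(axis=1)
    for tv in traits:
        if tv.values.size != n:
            raise ValueError("trait not aligned with phenotype table")
        keep &= np.isfinite(tv.values)

    if not keep.any():
        raise FilterError("sample filters removed every sample")
    screened = [tv.values for tv in traits]
    bmi_cols = [c for c in table.covariates if c.lower() == "bmi"]
    screened += [table.df[c].to_numpy(dtype=float) for c in bmi_cols]
    base = keep.copy()
    for values in screened:
        mu = values[base].mean()
        sd = values[base].std(ddof=1)
        if sd > 0:
            keep &= np.abs(values - mu) < sd_limit * sd
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        raise FilterError("sample filters removed every sample")
    return idx


def apply_variant_filters(
    block: GenotypeBlock,
    maf_min: float = 0.01,
    info_min: Optional[float] = 0.9,
) -> GenotypeBlock:
    """Keep variants with MAF strictly above ``maf_min`` and info strictly
    above ``info_min`` (skipped when the block carries no info scores or
    ``info_min`` is None). An empty result is allowed."""
    caf = block.caf
    with np.errstate(invalid="ignore"):
        maf = np.minimum(caf, 1.0 - caf)
        keep = np.isfinite(maf) & (maf > maf_min)
        if info_min is not None and block.info is not None:
            keep &= np.isfinite(block.info) & (block.info > info_min)
    return block.subset_variants(keep)


# ---------------------------------------------------------------------------
# results


def _fmt(value) -> str:
    if isinstance(value, (bool, np.bool_)):
        return str(int(value))
    if isinstance(value, (float, np.floating)):
        if math.isnan(value):
            return "NA"
        return f"{value:.10g}"
    return str(value)


def write_scan_results(rows: Sequence[dict], path) -> None:
    """Write scan records as TSV with the fixed column set ``SCAN_COLUMNS``."""
    with open(path, "w") as fh:
        fh.write("\t".join(SCAN_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(row[c]) for c in SCAN_COLUMNS) + "\n")


def read_scan_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])
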