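import numpy as np
import pandas as pd
import pytest

from vqtl.data_io import PhenotypeTable
from vqtl.mean_model import ResidualSet

VCF_TEXT = """\
##fileformat=VCFv4.2
##INFO=<ID=INFO,Number=1,Type=Float,Description="Imputation info score">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
1\t100\trs1\tG\tT\t.\t.\tINFO=0.95\tGT:DS\t0/0:0.1\t0/1:1.0\t1/1:1.9
1\t200\trs2\tA\tC\t.\t.\tINFO=0.99\tGT\t0/0\t0/1\t1/1
1\t300\trs3\tA\tG\t.\t.\t.\tGT\t./.\t0/1\t1/1
"""


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_vcf(tmp_path):
    path = tmp_path / "tiny.vcf"
    path.write_text(VCF_TEXT)
    return path


@pytest.fixture
def saturated_residuals():
    """The worked three-genotype example: e^2 = {1,3}, {2,6}, {4,12}."""
    e2 = np.array([1.0, 3.0, 2.0, 6.0, 4.0, 12.0])
    g = np.array([0.0, 0.0, 1.0, 1.0, 2.0, 2.0])
    return ResidualSet(residuals=np.sqrt(e2), n=6, genotype=g)


def make_bp_table(n=8, seed=0, medicated=None):
    r = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "sample_id": [f"S{i}" for i in range(n)],
            "sbp": r.normal(138, 18, n),
            "dbp": r.normal(82, 10, n),
            "medication": np.zeros(n) if medicated is None else np.asarray(medicated, float),
            "sex": r.binomial(1, 0.5, n).astype(float),
            "age": r.uniform(40, 69, n),
            "bmi": r.normal(27, 4, n),
        }
    )
    return PhenotypeTable(df=df, covariates=["sex", "age", "age2", "bmi"])


@pytest.fixture
def bp_table():
    return make_bp_table()
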