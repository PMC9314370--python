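"""Exception hierarchy for vqtl.

All errors raised by the library derive from :class:`VqtlError` so callers
(the scan driver, the CLI) can catch per-variant failures without masking
programming errors.
"""


class VqtlError(Exception):
    """Base class for all vqtl errors."""


class DataError(VqtlError):
    """Malformed or unusable input data (files, tables, genotype fields)."""


class MonomorphicVariantError(VqtlError):
    """Genotype vector is constant; no association model can be fit."""


class CollinearGenotypeError(VqtlError):
    """G and G^2 are collinear (fewer than three distinct genotype values)."""


class RankDeficiencyError(VqtlError):
    """Design matrix is rank deficient."""


class DegenerateResidualsError(VqtlError):
    """Residual variance is (numerically) zero; variance tests are undefined."""


class InfeasibleVarianceError(VqtlError):
    """Variance parameters imply a non-positive variance at an observed genotype."""


class FilterError(VqtlError):
    """A sample or variant filter removed everything."""


class GroupingError(VqtlError):
    """Too few usable genotype groups for a group-based test."""
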