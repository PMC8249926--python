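"""Core domain containers shared across the package.

The association machinery works on three simple objects: a vector of
minor-allele counts at one variant (:class:`GenotypeVector`), an N x M matrix
of quantitative phenotypes (:class:`PhenotypeMatrix`), and an optional N x P
covariate design (:class:`CovariateMatrix`).  Test output is collected in
:class:`AssociationResult`.  Containers are plain dataclasses wrapping numpy
arrays; validation happens at construction so downstream numerics can assume
clean input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GenotypeVector",
    "PhenotypeMatrix",
    "CovariateMatrix",
    "AssociationResult",
    "adjust_covariates",
]


@dataclass
class GenotypeVector:
    """Minor-allele dosages (0/1/2) for N individuals at one biallelic variant.

    Monomorphic vectors are representable (the association tests reject them,
    ingestion does not), but entries outside {0, 1, 2} are not.
    """

    counts: np.ndarray
    variant_id: str = "variant"
    maf_hint: float | None = None
    individual_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1 or self.counts.size < 2:
            raise ValueError("genotype vector must be 1-D with length >= 2")
        if not np.isin(self.counts, (0, 1, 2)).all():
            raise ValueError(
                f"{self.variant_id}: genotype entries must be 0, 1 or 2"
            )
        self.counts = self.counts.astype(np.int8)
        if self.maf_hint is not None and not 0 < self.maf_hint <= 0.5:
            raise ValueError("maf_hint must lie in (0, 0.5]")

    @property
    def n(self) -> int:
        return self.counts.size

    @property
    def allele_frequency(self) -> float:
        """In-sample frequency of the counted allele."""
        return float(self.counts.mean() / 2.0)

    @property
    def is_polymorphic(self) -> bool:
        return bool(self.counts.min() != self.counts.max())


@dataclass
class PhenotypeMatrix:
    """N x M matrix of quantitative phenotype values, complete cases only."""

    values: np.ndarray
    phenotype_names: list[str] | None = None
    individual_ids: list[str] | None = None
    n_excluded: int = 0

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        n, m = self.values.shape
        if n < 2:
            raise ValueError("phenotype matrix needs at least 2 individuals")
        if not np.isfinite(self.values).all():
            raise ValueError("phenotype matrix contains missing/non-finite values")
        if self.phenotype_names is None:
            self.phenotype_names = [f"pheno_{j}" for j in range(m)]
        if self.individual_ids is None:
            self.individual_ids = [str(i) for i in range(n)]
        if len(self.phenotype_names) != m or len(self.individual_ids) != n:
            raise ValueError("name/id lengths do not match matrix shape")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]

    def column_variances(self) -> np.ndarray:
        return self.values.var(axis=0, ddof=1)


@dataclass
class CovariateMatrix:
    """N x P covariate design (continuous or dummy-encoded categorical)."""

    values: np.ndarray
    covariate_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.covariate_names is None:
            self.covariate_names = [f"covar_{j}" for j in range(self.values.shape[1])]

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]


@dataclass
class AssociationResult:
    """Outcome of the clustered weighted-combination permutation test.

    ``t_wchc`` is the observed test statistic, the minimum of the K
    per-cluster permutation p-values; ``pvalue`` is its own permutation
    p-value.
    """

    variant_id: str
    K: int
    cluster_statistics: np.ndarray
    cluster_pvalues: np.ndarray
    t_wchc: float
    pvalue: float
    B: int
    seed: int | None
    method: str = "wchc"
    clusters: list[tuple[int, ...]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.cluster_statistics = np.asarray(self.cluster_statistics, dtype=float)
        self.cluster_pvalues = np.asarray(self.cluster_pvalues, dtype=float)
        if self.K < 1 or self.cluster_pvalues.size != self.K:
            raise ValueError("need K >= 1 cluster p-values")
        if not ((self.cluster_pvalues >= 0) & (self.cluster_pvalues <= 1)).all():
            raise ValueError("cluster p-values outside [0, 1]")
        if not 0 <= self.pvalue <= 1:
            raise ValueError("p-value outside [0, 1]")
        if not np.isclose(self.t_wchc, self.cluster_pvalues.min()):
            raise ValueError("t_wchc must equal the minimum cluster p-value")


def adjust_covariates(
    phenotypes: PhenotypeMatrix, covariates: CovariateMatrix | None
) -> PhenotypeMatrix:
    """Replace each phenotype by its OLS residual on [intercept, covariates].

    With an empty covariate set this is plain column centering.  The residual
    columns are exactly orthogonal to the intercept and to every covariate
    column (up to numerical round-off), which is what downstream tests rely on
    when covariate effects must not masquerade as genetic signal.
    """
    y = phenotypes.values
    n = y.shape[0]
    if covariates is None or covariates.p == 0:
        resid = y - y.mean(axis=0)
    else:
        if covariates.n != n:
            raise ValueError("phenotype and covariate row counts differ")
        design = np.column_stack([np.ones(n), covariates.values])
        if n <= design.shape[1]:
            raise ValueError("too few individuals for the covariate design")
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError("covariate design (with intercept) is rank deficient")
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
    return PhenotypeMatrix(
        values=resid,
        phenotype_names=list(phenotypes.phenotype_names),
        individual_ids=list(phenotypes.individual_ids),
        n_excluded=phenotypes.n_excluded,
    )
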