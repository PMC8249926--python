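"""The weighted-combination permutation test (WCHC / WCmulP).

For one biallelic variant each individual's genotype g_i ∈ {0,1,2} is expanded
into two binary allele indicators x (AA → (1,1), Aa → (1,0), aa → (0,0)) and
the phenotype rows are duplicated, giving 2N allele records.  Within a
phenotype cluster the statistic is

    T = Σ_l (x_l − x̄)(y_l − ȳ),   y_l = Σ_j w_j y_{l,j},
    w_j = Σ_l (x_l − x̄)(y_{l,j} − ȳ_j) / Σ_l (y_{l,j} − ȳ_j)²,

i.e. the score of the optimally weighted phenotype combination, motivated by
the allele-based logistic model logit P(x_l = 1 | y_l) = β0 + Σ β_j y_{l,j}
(the logistic model is never fitted; the statistic is computed directly).
Algebraically T = Σ_j c_j²/v_j with c_j the centred x–y_j cross sum and v_j
the centred sum of squares of y_j, hence T ≥ 0; that identity is the primary
correctness oracle and also the form used by the batched permutation path.

The global statistic is T_WCHC = min_k p_k over the per-cluster permutation
p-values, and its own p-value comes from the same B genotype permutations:

    p_k^(b) = #{d = 0..B : T_k^(d) > T_k^(b)} / B
    p(T_WCHC) = #{b = 1..B : T_WCHC^(b) < T_WCHC^(0)} / B

with b = 0 the unpermuted data.  Genotypes are permuted at the individual
level; weights are recomputed inside every permutation (they depend on x).
WCmulP is the K = 1 special case with all phenotypes in one cluster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .clustering import ClusterPartition, cluster_phenotypes
from .data import AssociationResult, GenotypeVector, PhenotypeMatrix

__all__ = [
    "ExpandedDesign",
    "ClusterStatistic",
    "PermutationResult",
    "allele_expand",
    "combination_weights",
    "cluster_statistic",
    "permute_genotypes",
    "wchc_test",
    "wcmulp_test",
    "run_wchc",
]


@dataclass
class ExpandedDesign:
    """Allele-level design: binary x of length 2N, duplicated phenotype rows."""

    x: np.ndarray
    y: np.ndarray
    n_individuals: int

    def rows_of(self, i: int) -> tuple[int, int]:
        """Row indices of individual i's two allele records."""
        return 2 * i, 2 * i + 1


@dataclass
class ClusterStatistic:
    cluster_index: int
    weights: np.ndarray
    T: float


@dataclass
class PermutationResult:
    """Full permutation trace; row b = 0 is the unpermuted data."""

    B: int
    statistics: np.ndarray  # (K, B+1)
    cluster_pvalues: np.ndarray  # (K, B+1)
    t_wchc: np.ndarray  # (B+1,)
    pvalue: float


def allele_expand(g: GenotypeVector | np.ndarray, phenotypes) -> ExpandedDesign:
    """Expand genotype counts to 2N allele indicators, duplicating phenotypes.

    A heterozygote contributes rows (1, 0); their order is immaterial because
    every downstream statistic depends on the genotype count only.
    """
    counts = np.asarray(getattr(g, "counts", g))
    y = np.atleast_2d(np.asarray(getattr(phenotypes, "values", phenotypes), float))
    n = counts.size
    if y.shape[0] != n:
        raise ValueError("genotype and phenotype lengths differ")
    if not np.isin(counts, (0, 1, 2)).all():
        raise ValueError("genotype entries must be 0, 1 or 2")
    x = np.zeros(2 * n)
    x[0::2] = np.minimum(counts, 1)  # first allele: 1 unless aa
    x[1::2] = np.maximum(counts - 1, 0)  # second allele: 1 only for AA
    return ExpandedDesign(x=x, y=np.repeat(y, 2, axis=0), n_individuals=n)


def combination_weights(
    design: ExpandedDesign, cluster: tuple[int, ...] | list[int]
) -> np.ndarray:
    """Per-phenotype combination weights w_j over the 2N allele records."""
    idx = list(cluster)
    xc = design.x - design.x.mean()
    yc = design.y[:, idx] - design.y[:, idx].mean(axis=0)
    denom = (yc**2).sum(axis=0)
    if (denom <= 0).any():
        j = idx[int(np.argmin(denom))]
        raise ValueError(f"phenotype {j} has zero variance; weight undefined")
    return (xc @ yc) / denom


def cluster_statistic(
    design: ExpandedDesign, cluster: tuple[int, ...] | list[int], k: int = 0
) -> ClusterStatistic:
    """T for one cluster, computed from the weighted combination definition."""
    idx = list(cluster)
    w = combination_weights(design, cluster)
    ycomb = design.y[:, idx] @ w
    xc = design.x - design.x.mean()
    T = float(xc @ (ycomb - ycomb.mean()))
    return ClusterStatistic(cluster_index=k, weights=w, T=T)


def permute_genotypes(
    g: GenotypeVector | np.ndarray, rng: np.random.Generator
) -> GenotypeVector:
    """Uniform random permutation of the N genotype counts."""
    counts = np.asarray(getattr(g, "counts", g))
    vid = getattr(g, "variant_id", "variant")
    return GenotypeVector(counts=rng.permutation(counts), variant_id=vid)


def _validate_test_inputs(g, phenotypes) -> tuple[np.ndarray, np.ndarray]:
    counts = np.asarray(getattr(g, "counts", g))
    y = np.atleast_2d(np.asarray(getattr(phenotypes, "values", phenotypes), float))
    if counts.size != y.shape[0]:
        raise ValueError("genotype and phenotype lengths differ")
    if counts.min() == counts.max():
        raise ValueError("monomorphic genotype: statistic undefined")
    if (y.var(axis=0) <= 0).any():
        raise ValueError("zero-variance phenotype column")
    return counts, y


def _batched_statistics(
    gstack: np.ndarray, y: np.ndarray, clusters: list[tuple[int, ...]]
) -> np.ndarray:
    """T_k for each genotype row of ``gstack`` via the Σ_j c_j²/v_j identity.

    Over the 2N expansion c_j collapses to the N-level centred cross sum and
    v_j to twice the N-level centred sum of squares, so no expansion is
    materialised.
    """
    yc = y - y.mean(axis=0)
    v2 = 2.0 * (yc**2).sum(axis=0)  # v_j over 2N rows
    gc = gstack - gstack.mean(axis=1, keepdims=True)
    contrib = (gc @ yc) ** 2 / v2  # (B+1, M) per-phenotype c_j² / v_j
    return np.stack([contrib[:, list(c)].sum(axis=1) for c in clusters])


def _permutation_pvalues(T: np.ndarray, B: int) -> np.ndarray:
    """p_k^(b) = #{d : T_k^(d) > T_k^(b)} / B for every b, vectorised per k."""
    P = np.empty_like(T)
    for k in range(T.shape[0]):
        s = np.sort(T[k])
        P[k] = (T.shape[1] - np.searchsorted(s, T[k], side="right")) / B
    return P


def wchc_test(
    g: GenotypeVector | np.ndarray,
    phenotypes: PhenotypeMatrix | np.ndarray,
    partition: ClusterPartition | list | None,
    B: int = 1000,
    seed: int | None = None,
    add_one: bool = False,
    return_trace: bool = False,
):
    """Clustered weighted-combination permutation test for one variant.

    ``partition`` fixes the phenotype clusters (computed once from the
    observed phenotypes, never from genotypes); pass ``None`` for the trivial
    single cluster.  ``add_one`` switches the final p-value to the
    (r + 1)/(B + 1) estimator; the default keeps the plain r/B count, which
    permits p = 0.  Fixed ``seed`` gives bit-identical results.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    counts, y = _validate_test_inputs(g, phenotypes)
    n = counts.size
    m = y.shape[1]
    if partition is None:
        partition = ClusterPartition.trivial(m)
    clusters = (
        partition.clusters
        if isinstance(partition, ClusterPartition)
        else [tuple(c) for c in partition]
    )
    covered = sorted(i for c in clusters for i in c)
    if covered != list(range(m)):
        raise ValueError("partition does not cover the phenotypes")

    rng = np.random.default_rng(seed)
    gstack = np.empty((B + 1, n))
    gstack[0] = counts
    for b in range(1, B + 1):
        gstack[b] = counts[rng.permutation(n)]

    T = _batched_statistics(gstack, y, clusters)
    P = _permutation_pvalues(T, B)
    t_wchc = P.min(axis=0)
    r = int(np.sum(t_wchc[1:] < t_wchc[0]))
    pvalue = (r + 1) / (B + 1) if add_one else r / B

    result = AssociationResult(
        variant_id=getattr(g, "variant_id", "variant"),
        K=len(clusters),
        cluster_statistics=T[:, 0],
        cluster_pvalues=P[:, 0],
        t_wchc=float(t_wchc[0]),
        pvalue=float(pvalue),
        B=B,
        seed=seed,
        method="wchc" if len(clusters) > 1 else "wcmulp",
        clusters=[tuple(c) for c in clusters],
    )
    if return_trace:
        trace = PermutationResult(
            B=B, statistics=T, cluster_pvalues=P, t_wchc=t_wchc, pvalue=float(pvalue)
        )
        return result, trace
    return result


def wcmulp_test(
    g: GenotypeVector | np.ndarray,
    phenotypes: PhenotypeMatrix | np.ndarray,
    B: int = 1000,
    seed: int | None = None,
    add_one: bool = False,
) -> AssociationResult:
    """Weighted combination of all M phenotypes without clustering (K = 1)."""
    y = np.atleast_2d(np.asarray(getattr(phenotypes, "values", phenotypes), float))
    return wchc_test(
        g, phenotypes, ClusterPartition.trivial(y.shape[1]), B=B, seed=seed,
        add_one=add_one,
    )


def run_wchc(
    g: GenotypeVector | np.ndarray,
    phenotypes: PhenotypeMatrix | np.ndarray,
    B: int = 1000,
    seed: int | None = None,
    add_one: bool = False,
) -> AssociationResult:
    """Full pipeline: cluster the phenotypes, then run the permutation test."""
    partition = cluster_phenotypes(phenotypes)
    return wchc_test(g, phenotypes, partition, B=B, seed=seed, add_one=add_one)
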