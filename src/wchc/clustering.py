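"""Bottom-up hierarchical clustering of phenotypes.

Phenotypes are agglomerated by a size-dependent correlation similarity:
|Pearson| between two singletons, the multiple correlation coefficient when a
singleton meets a block, and the first canonical correlation between two
blocks.  The stopping rule picks the iteration b̂ minimising the height
difference h_{b+1} − h_b (the largest drop in merge similarity) and returns
the K = M − b̂ clusters present at that point.

All three similarity measures are functions of the M x M phenotype
correlation matrix alone, so the agglomeration works on that matrix; the
column-level entry points (:func:`pairwise_similarity`,
:func:`cluster_similarity`) evaluate the same quantities from raw data.
Similarity involving a freshly merged block is recomputed exactly at every
iteration — there is no Lance–Williams update for canonical correlation — so
heights need not be monotone and the stopping rule does not assume they are.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DendrogramTrace",
    "ClusterPartition",
    "pairwise_similarity",
    "cluster_similarity",
    "agglomerate",
    "select_partition",
    "cluster_phenotypes",
]


@dataclass
class DendrogramTrace:
    """Ordered merge record: (members_a, members_b, height) per iteration."""

    merges: list[tuple[tuple[int, ...], tuple[int, ...], float]]
    M: int

    def heights(self) -> np.ndarray:
        return np.array([h for _, _, h in self.merges])


@dataclass
class ClusterPartition:
    """Disjoint grouping of the M phenotype indices into K clusters."""

    clusters: list[tuple[int, ...]]
    M: int
    b_hat: int

    def __post_init__(self) -> None:
        members = sorted(i for c in self.clusters for i in c)
        if members != list(range(self.M)):
            raise ValueError("clusters must partition the phenotype indices")

    @property
    def K(self) -> int:
        return len(self.clusters)

    @classmethod
    def trivial(cls, M: int) -> "ClusterPartition":
        """The single all-phenotype cluster (no clustering step)."""
        return cls(clusters=[tuple(range(M))], M=M, b_hat=M - 1)


def _check_columns(y: np.ndarray) -> np.ndarray:
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if y.shape[1] > y.shape[0] and y.ndim == 2 and min(y.shape) == 1:
        y = y.T
    if (y.var(axis=0) <= 0).any():
        raise ValueError("zero-variance phenotype column")
    return y


def _block_similarity(
    corr: np.ndarray, a: tuple[int, ...], b: tuple[int, ...]
) -> float:
    """Similarity of two disjoint index blocks from the correlation matrix.

    1-vs-1: |r|.  1-vs-many: multiple correlation of the singleton on the
    block, sqrt(r' R_bb^{-1} r).  many-vs-many: first canonical correlation,
    the largest singular value of R_aa^{-1/2} R_ab R_bb^{-1/2}.
    """
    if len(a) == 1 and len(b) == 1:
        return abs(float(corr[a[0], b[0]]))
    if len(b) == 1:
        a, b = b, a
    if len(a) == 1:
        r = corr[np.ix_(b, a)].ravel()
        rbb = corr[np.ix_(b, b)]
        try:
            sol = np.linalg.solve(rbb, r)
        except np.linalg.LinAlgError as e:
            raise ValueError("singular within-block covariance") from e
        r2 = float(r @ sol)
        return float(np.sqrt(min(max(r2, 0.0), 1.0)))
    raa = corr[np.ix_(a, a)]
    rbb = corr[np.ix_(b, b)]
    rab = corr[np.ix_(a, b)]
    try:
        la = np.linalg.cholesky(raa)
        lb = np.linalg.cholesky(rbb)
    except np.linalg.LinAlgError as e:
        raise ValueError("singular within-block covariance") from e
    m = np.linalg.solve(la, rab)
    m = np.linalg.solve(lb, m.T).T
    s = np.linalg.svd(m, compute_uv=False)
    return float(min(s[0], 1.0))


def pairwise_similarity(y_a: np.ndarray, y_b: np.ndarray) -> float:
    """|Pearson correlation| between two phenotype columns."""
    y_a = np.asarray(y_a, dtype=float).ravel()
    y_b = np.asarray(y_b, dtype=float).ravel()
    if y_a.size != y_b.size:
        raise ValueError("columns must have equal length")
    if y_a.var() <= 0 or y_b.var() <= 0:
        raise ValueError("zero-variance phenotype column")
    r = np.corrcoef(y_a, y_b)[0, 1]
    return abs(float(r))


def cluster_similarity(block_a: np.ndarray, block_b: np.ndarray) -> float:
    """Similarity between two phenotype blocks given their raw columns."""
    a = _check_columns(block_a)
    b = _check_columns(block_b)
    if a.shape[0] != b.shape[0]:
        raise ValueError("blocks must have equal numbers of rows")
    pa, pb = a.shape[1], b.shape[1]
    corr = np.corrcoef(np.column_stack([a, b]), rowvar=False)
    return _block_similarity(corr, tuple(range(pa)), tuple(range(pa, pa + pb)))


def agglomerate(phenotypes) -> DendrogramTrace:
    """Merge phenotype clusters greedily by largest similarity.

    Ties break to the lexicographically smallest pair of smallest member
    indices, making the trace deterministic under column permutation.
    """
    y = getattr(phenotypes, "values", phenotypes)
    y = np.atleast_2d(np.asarray(y, dtype=float))
    M = y.shape[1]
    if M < 2:
        raise ValueError("need at least 2 phenotypes to cluster")
    if (y.var(axis=0) <= 0).any():
        raise ValueError("zero-variance phenotype column")
    corr = np.corrcoef(y, rowvar=False)
    return _agglomerate_corr(corr)


def _agglomerate_corr(corr: np.ndarray) -> DendrogramTrace:
    M = corr.shape[0]
    # clusters kept sorted by smallest member; similarities cached per pair and
    # recomputed only for pairs involving the latest merge
    clusters: list[tuple[int, ...]] = [(j,) for j in range(M)]
    sim: dict[frozenset[tuple[int, ...]], float] = {
        frozenset((clusters[i], clusters[j])): abs(float(corr[i, j]))
        for i in range(M)
        for j in range(i + 1, M)
    }
    merges: list[tuple[tuple[int, ...], tuple[int, ...], float]] = []
    while len(clusters) > 1:
        best_key = None
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                s = sim[frozenset((clusters[i], clusters[j]))]
                key = (-s, clusters[i][0], clusters[j][0])
                if best_key is None or key < best_key:
                    best_key = key
                    best = (clusters[i], clusters[j], s)
        a, b, h = best  # type: ignore[misc]
        merged = tuple(sorted(a + b))
        merges.append((a, b, h))
        clusters = [c for c in clusters if c not in (a, b)]
        sim = {k: v for k, v in sim.items() if a not in k and b not in k}
        for c in clusters:
            sim[frozenset((c, merged))] = _block_similarity(corr, c, merged)
        clusters.append(merged)
        clusters.sort(key=lambda c: c[0])
    return DendrogramTrace(merges=merges, M=M)


def select_partition(trace: DendrogramTrace) -> ClusterPartition:
    """Apply the largest-drop stopping rule to a merge trace.

    b̂ = argmin_b (h_{b+1} − h_b) over b = 1..M−2 (ties to the smallest b,
    i.e. more clusters); the partition is the cluster set existing after
    iteration b̂, so K = M − b̂.  For M = 2 the rule is undefined and the
    single two-phenotype cluster is returned.
    """
    M = trace.M
    h = trace.heights()
    if M == 2:
        b_hat = 1
    else:
        diffs = h[1:] - h[:-1]  # index b-1 holds h_{b+1} - h_b
        b_hat = int(np.argmin(diffs)) + 1
    clusters: list[tuple[int, ...]] = [(j,) for j in range(M)]
    for a, b, _ in trace.merges[:b_hat]:
        clusters = [c for c in clusters if c not in (a, b)]
        clusters.append(tuple(sorted(a + b)))
    clusters.sort(key=lambda c: c[0])
    return ClusterPartition(clusters=clusters, M=M, b_hat=b_hat)


def write_trace(trace: DendrogramTrace, path, partition: ClusterPartition | None = None) -> None:
    """Export the merge trace (and optionally the chosen partition) as TSV."""
    with open(path, "w") as fh:
        fh.write("iteration\tmembers_a\tmembers_b\theight\n")
        for b, (a, c, h) in enumerate(trace.merges, start=1):
            fh.write(
                f"{b}\t{','.join(map(str, a))}\t{','.join(map(str, c))}\t{h:.10g}\n"
            )
        if partition is not None:
            fh.write(f"# b_hat={partition.b_hat}\tK={partition.K}\t")
            fh.write("clusters=" + ";".join(
                ",".join(map(str, c)) for c in partition.clusters
            ) + "\n")


def cluster_phenotypes(phenotypes) -> ClusterPartition:
    """Agglomerate and apply the stopping rule in one call."""
    y = getattr(phenotypes, "values", phenotypes)
    if np.asarray(y).shape[1] == 1:
        return ClusterPartition(clusters=[(0,)], M=1, b_hat=0)
    return select_partition(agglomerate(phenotypes))
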