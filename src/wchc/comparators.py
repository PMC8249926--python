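"""Comparator association tests: O'Brien, SHet, TATES, MANOVA, MultiPhen.

All comparators except MANOVA/MultiPhen act on a shared vector of univariate
score statistics: t_j is the z-scale statistic of the simple linear regression
of phenotype j on genotype dosage, whose null correlation matrix is estimated
by the phenotype correlation matrix.  WCmulP (the sixth comparator) lives in
:mod:`wchc.core` as the K = 1 weighted-combination test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import GenotypeVector, PhenotypeMatrix

__all__ = [
    "UnivariateStats",
    "univariate_stats",
    "obrien_test",
    "shet_test",
    "tates_test",
    "manova_test",
    "multiphen_test",
]

_T_CAP = 1e8  # guard for perfect fits (r^2 -> 1)


@dataclass
class UnivariateStats:
    """Per-phenotype score statistics and their estimated null covariance."""

    t: np.ndarray  # (M,) z-scale statistics
    Sigma: np.ndarray  # (M, M) covariance of t (== Corr on the z scale)
    Corr: np.ndarray  # (M, M) correlation of t
    W: np.ndarray  # (M, M) diagonal weights
    p: np.ndarray  # (M,) two-sided normal p-values
    n: int


def _as_arrays(g, phenotypes) -> tuple[np.ndarray, np.ndarray]:
    counts = np.asarray(getattr(g, "counts", g), dtype=float)
    y = np.atleast_2d(np.asarray(getattr(phenotypes, "values", phenotypes), float))
    if counts.size != y.shape[0]:
        raise ValueError("genotype and phenotype lengths differ")
    if counts.min() == counts.max():
        raise ValueError("monomorphic genotype")
    return counts, y


def univariate_stats(
    g: GenotypeVector | np.ndarray, phenotypes: PhenotypeMatrix | np.ndarray
) -> UnivariateStats:
    """Simple-regression score statistics t_j for each phenotype.

    t_j = r_j sqrt(N−2)/sqrt(1−r_j²) with r_j the genotype–phenotype sample
    correlation; asymptotically standard normal under the null.  Perfect fits
    are capped rather than returned infinite.
    """
    counts, y = _as_arrays(g, phenotypes)
    n = counts.size
    gc = counts - counts.mean()
    yc = y - y.mean(axis=0)
    sy = np.sqrt((yc**2).sum(axis=0))
    if (sy <= 0).any():
        raise ValueError("zero-variance phenotype column")
    r = (gc @ yc) / (np.linalg.norm(gc) * sy)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r**2)
    t = np.clip(np.nan_to_num(t, nan=0.0, posinf=_T_CAP, neginf=-_T_CAP),
                -_T_CAP, _T_CAP)
    corr = np.corrcoef(y, rowvar=False)
    corr = np.atleast_2d(corr)
    p = 2.0 * stats.norm.sf(np.abs(t))
    m = y.shape[1]
    return UnivariateStats(
        t=t, Sigma=corr.copy(), Corr=corr, W=np.eye(m), p=p, n=n
    )


def obrien_test(ustats: UnivariateStats) -> tuple[float, float]:
    """O'Brien's linear combination 1'Σ⁻¹t, standardised by 1'Σ⁻¹1.

    Returns the standardised statistic and its two-sided normal p-value.
    Optimal when the per-phenotype effects are homogeneous.
    """
    m = ustats.t.size
    ones = np.ones(m)
    try:
        sol = np.linalg.solve(ustats.Sigma, np.column_stack([ustats.t, ones]))
    except np.linalg.LinAlgError as e:
        raise ValueError("singular score covariance (duplicated phenotypes?)") from e
    s = float(ones @ sol[:, 0])
    var = float(ones @ sol[:, 1])
    if var <= 0:
        raise ValueError("non-positive variance of the combined statistic")
    z = s / np.sqrt(var)
    return z, float(2.0 * stats.norm.sf(abs(z)))


def _shom_prefix_stats(tmat: np.ndarray, corr: np.ndarray, w: np.ndarray):
    """S_Hom on every prefix of each row's own descending-|t| order.

    Permuting Corr into that order makes the threshold-selected subsets
    prefixes, and the Cholesky factor of the permuted matrix contains the
    factors of all leading blocks; two triangular solves then yield every
    prefix statistic via cumulative sums.  Returns (prefix stats (n, M),
    |t| sorted descending (n, M)).
    """
    tmat = np.atleast_2d(tmat)
    n, m = tmat.shape
    order = np.argsort(-np.abs(tmat), axis=1, kind="stable")
    tp = np.take_along_axis(tmat, order, axis=1)
    wd = np.diag(w)
    wp = wd[order]  # (n, M) diagonal weights in permuted order
    cp = corr[order[:, :, None], order[:, None, :]]
    try:
        L = np.linalg.cholesky(cp)
    except np.linalg.LinAlgError as e:
        raise ValueError("score correlation matrix is not positive definite") from e
    # S_Hom(S) = (1' (Corr W)^-1 t)^2 / (1' (W Corr W)^-1 1) on the subset S;
    # with u = L^-1 W^-1 1 and z = L^-1 t the prefix numerator is cumsum(u z)
    # and the prefix denominator cumsum(u^2).
    rhs = np.stack([1.0 / wp, tp], axis=2)
    sol = np.linalg.solve(L, rhs)
    u, z = sol[..., 0], sol[..., 1]
    num = np.cumsum(u * z, axis=1) ** 2
    den = np.cumsum(u * u, axis=1)
    return num / den, np.abs(tp)


def shet_test(
    ustats: UnivariateStats,
    thresholds: np.ndarray | None = None,
    n_mc: int = 10000,
    seed: int | None = None,
) -> tuple[float, float]:
    """SHet: maximum of threshold-restricted homogeneous statistics.

    S_Hom(τ) uses only the statistics with |t_j| > τ together with the
    matching sub-blocks of Corr and W; S_Het is the maximum over the
    threshold grid (default: 0 plus the sorted unique observed |t_j|).  Its
    p-value is Monte-Carlo: n_mc draws of t from MVN(0, Corr), each pushed
    through the same grid and maximum.
    """
    t, corr, w = ustats.t, ustats.Corr, ustats.W
    m = t.size
    if thresholds is None:
        thresholds = np.concatenate([[0.0], np.unique(np.abs(t))])
    thresholds = np.asarray(thresholds, dtype=float)

    def s_het(tmat: np.ndarray) -> np.ndarray:
        prefix, abs_sorted = _shom_prefix_stats(tmat, corr, w)
        # subset size for each threshold = # |t| strictly above it
        counts = (abs_sorted[:, None, :] > thresholds[None, :, None]).sum(axis=2)
        take = np.clip(counts - 1, 0, m - 1)
        vals = np.take_along_axis(prefix, take, axis=1)
        vals = np.where(counts > 0, vals, -np.inf)
        out = vals.max(axis=1)
        if np.isneginf(out).any():
            raise ValueError("no statistic exceeds any threshold")
        return out

    s_obs = float(s_het(t[None, :])[0])
    rng = np.random.default_rng(seed)
    try:
        L = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as e:
        raise ValueError("score correlation matrix is not positive definite") from e
    draws = rng.standard_normal((n_mc, m)) @ L.T
    s_null = s_het(draws)
    pvalue = float(np.sum(s_null >= s_obs) / n_mc)
    return s_obs, pvalue


# Sixth-degree polynomial mapping the phenotype correlation r to the
# correlation between the two-sided univariate p-values, as published with
# the extended-Simes procedures (Li et al. 2011 GATES; adopted by TATES, van
# der Sluis et al. 2013).  Applied to |r|: two-sided p-values are invariant
# to the correlation's sign.  Verified in the test suite against the
# empirical correlation of p-values from correlated null z-scores.
_TATES_POLY = (0.2982, -0.0127, 0.0588, 0.0099, 0.6281, -0.0009, 0.0)


def _effective_number(corr_p: np.ndarray) -> float:
    """Eigenvalue-based effective number of independent p-values."""
    lam = np.linalg.eigvalsh(corr_p)
    if lam.min() < -1e-8:
        warnings.warn("p-value correlation not PSD; clipping eigenvalues at 0")
    lam = np.clip(lam, 0.0, None)
    return float(corr_p.shape[0] - np.sum(np.where(lam > 1, lam - 1, 0.0)))


def tates_test(
    p: np.ndarray, pheno_corr: np.ndarray
) -> float:
    """TATES extended-Simes combination of per-phenotype p-values.

    p_TATES = min_j M_e p_(j) / M_e(j), with effective numbers computed from
    the p-value correlation matrix implied by the phenotype correlations.
    Reduces exactly to the Simes procedure when the correlation is identity.
    """
    p = np.asarray(p, dtype=float).ravel()
    m = p.size
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    if m == 1:
        return float(p[0])
    pheno_corr = np.atleast_2d(np.asarray(pheno_corr, dtype=float))
    order = np.argsort(p, kind="stable")
    ps = p[order]
    r = np.abs(pheno_corr[order][:, order])
    corr_p = np.polyval(_TATES_POLY, r)
    np.fill_diagonal(corr_p, 1.0)
    me = _effective_number(corr_p)
    ratios = np.empty(m)
    for j in range(1, m + 1):
        me_j = _effective_number(corr_p[:j, :j])
        ratios[j - 1] = me * ps[j - 1] / me_j
    return float(min(ratios.min(), 1.0))


def manova_test(
    g: GenotypeVector | np.ndarray, phenotypes: PhenotypeMatrix | np.ndarray
) -> tuple[float, float]:
    """One-predictor MANOVA: Wilks' Λ with Rao's F approximation.

    For a single regressor Λ = 1 − R² where R² is the squared multiple
    correlation of the dosage on the M phenotypes, and
    F = (1 − Λ)/Λ · (N − M − 1)/M ~ F(M, N − M − 1) exactly.
    Returns (Λ, p-value).
    """
    counts, y = _as_arrays(g, phenotypes)
    n, m = y.shape
    if n <= m + 2:
        raise ValueError("need N > M + 2 for MANOVA")
    yc = y - y.mean(axis=0)
    gc = counts - counts.mean()
    syy = yc.T @ yc
    syg = yc.T @ gc
    try:
        sol = np.linalg.solve(syy, syg)
    except np.linalg.LinAlgError as e:
        raise ValueError("singular residual covariance (collinear phenotypes)") from e
    r2 = float(syg @ sol) / float(gc @ gc)
    cond = np.linalg.cond(syy)
    if cond > 1e12:
        raise ValueError("singular residual covariance (collinear phenotypes)")
    r2 = min(max(r2, 0.0), 1.0 - 1e-15)
    lam = 1.0 - r2
    f = (r2 / lam) * (n - m - 1) / m
    pvalue = float(stats.f.sf(f, m, n - m - 1))
    return lam, pvalue


def multiphen_test(
    g: GenotypeVector | np.ndarray, phenotypes: PhenotypeMatrix | np.ndarray
) -> tuple[float, float]:
    """MultiPhen: proportional-odds regression of dosage on the phenotypes.

    The genotype is the ordinal response (levels absent in-sample collapse the
    cut-points); the likelihood-ratio statistic against the intercept-only
    model is referred to χ²_M.  Returns (LRT, p-value); non-convergence
    returns (nan, nan) with a warning.
    """
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    counts, y = _as_arrays(g, phenotypes)
    n, m = y.shape
    if n <= m + 2:
        raise ValueError("need N > M + 2 for MultiPhen")
    levels, inverse = np.unique(counts, return_inverse=True)
    # null log-likelihood: cut-points only => multinomial at observed freqs
    freqs = np.bincount(inverse) / n
    llf0 = float(np.sum(np.bincount(inverse) * np.log(freqs)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = OrderedModel(inverse.astype(float), y, distr="logit")
        try:
            res = model.fit(method="lbfgs", disp=False, maxiter=200)
        except Exception as e:  # separation / numerical failure
            warnings.warn(f"MultiPhen fit failed: {e}")
            return float("nan"), float("nan")
    if not res.mle_retvals.get("converged", True):
        warnings.warn("MultiPhen ordinal fit did not converge")
        return float("nan"), float("nan")
    lrt = 2.0 * (res.llf - llf0)
    lrt = max(float(lrt), 0.0)
    return lrt, float(stats.chi2.sf(lrt, m))
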