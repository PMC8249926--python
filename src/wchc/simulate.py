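"""Generative model for the simulation study.

Genotypes are Hardy–Weinberg draws, g_i ~ Binomial(2, MAF).  Phenotypes come
from the factor model

    y = λ x + c γ f + sqrt(1 − c²) ε,

with f ~ MVN(0, (1 − ρ)I_R + ρ 1 1') latent factors shared within blocks of
the loading matrix γ (block-diagonal all-ones pattern) and ε standard normal
noise.  Marginal phenotype variance is 1 under the null, the within-factor
phenotype correlation is c² and the between-factor correlation is ρc².  Six
genetic architectures (``model_config``) place the variant's effects λ on
all, half, or a quarter of the phenotypes, with equal, graded, or opposing
sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import GenotypeVector, PhenotypeMatrix

__all__ = [
    "SimulationSpec",
    "simulate_genotypes",
    "model_config",
    "simulate_phenotypes",
    "heritability",
    "simulate_dataset",
]


@dataclass
class SimulationSpec:
    """Factor-model parameters for one simulation scenario."""

    model_id: int
    M: int
    R: int
    beta: float
    lam: np.ndarray  # (M,) effect sizes λ
    gamma: np.ndarray  # (M, R) block loading pattern
    c: float  # within-factor loading; within-factor correlation is c²
    rho: float  # factor correlation; between-factor correlation is ρc²
    maf: float = 0.3
    N: int = 1000

    def __post_init__(self) -> None:
        self.lam = np.asarray(self.lam, dtype=float)
        self.gamma = np.atleast_2d(np.asarray(self.gamma, dtype=float))
        if self.gamma.shape != (self.M, self.R):
            raise ValueError("gamma must be M x R")
        if not 0 <= self.c <= 1:
            raise ValueError("c must lie in [0, 1]")
        if not 0 <= self.rho <= 1:
            raise ValueError("rho must lie in [0, 1]")
        if not 0 < self.maf <= 0.5:
            raise ValueError("maf must lie in (0, 0.5]")

    @property
    def c2(self) -> float:
        return self.c**2

    @property
    def rho_c2(self) -> float:
        return self.rho * self.c**2


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_genotypes(N: int, maf: float, seed=None) -> GenotypeVector:
    """N iid Hardy–Weinberg genotype counts, Binomial(2, maf)."""
    if not 0 < maf <= 0.5:
        raise ValueError("maf must lie in (0, 0.5]")
    rng = _as_rng(seed)
    return GenotypeVector(
        counts=rng.binomial(2, maf, size=N), variant_id="sim", maf_hint=maf
    )


def _block_gamma(M: int, R: int) -> np.ndarray:
    size = M // R
    gamma = np.zeros((M, R))
    for r in range(R):
        gamma[r * size : (r + 1) * size, r] = 1.0
    return gamma


def model_config(
    model_id: int,
    M: int,
    beta: float,
    c2: float = 0.5,
    rho_c2: float = 0.1,
    maf: float = 0.3,
    N: int = 1000,
) -> SimulationSpec:
    """Effect-size vector λ and loadings γ for architectures 1–6.

    1: one factor, equal effect on all phenotypes.
    2: two factors, equal effect on the second factor's phenotypes.
    3: two factors, graded effects β(j/(M+1) + 1) on the second block.
    4: four factors, equal effect on the last block.
    5: four factors, graded effects on the last block.
    6: four factors, graded negative effects on the third block and equal
       positive effects on the fourth (opposing directions).

    ``c2`` and ``rho_c2`` are the target within-/between-factor phenotype
    correlations; the factor correlation is recovered as ρ = rho_c2 / c2.
    """
    blocks = {1: 1, 2: 2, 3: 2, 4: 4, 5: 4, 6: 4}
    if model_id not in blocks:
        raise ValueError("model_id must be in 1..6")
    R = blocks[model_id]
    if M % R:
        raise ValueError(f"M must be divisible by {R} for model {model_id}")
    if not 0 < c2 <= 1:
        raise ValueError("c2 must lie in (0, 1]")
    half, quarter = M // 2, M // 4
    if model_id == 1:
        lam = np.full(M, beta)
    elif model_id == 2:
        lam = np.concatenate([np.zeros(half), np.full(half, beta)])
    elif model_id == 3:
        j = np.arange(1, half + 1)
        lam = np.concatenate([np.zeros(half), beta * j / (M + 1) + beta])
    elif model_id == 4:
        lam = np.concatenate([np.zeros(3 * quarter), np.full(quarter, beta)])
    elif model_id == 5:
        j = np.arange(1, quarter + 1)
        lam = np.concatenate(
            [np.zeros(3 * quarter), beta * j / (M + 1) + beta]
        )
    else:  # model 6
        j = np.arange(1, quarter + 1)
        lam = np.concatenate(
            [
                np.zeros(half),
                -beta * j / (M + 1) - beta,
                np.full(quarter, beta),
            ]
        )
    c = float(np.sqrt(c2))
    rho = float(rho_c2 / c2)
    if not 0 <= rho <= 1:
        raise ValueError("rho_c2 / c2 must lie in [0, 1]")
    return SimulationSpec(
        model_id=model_id, M=M, R=R, beta=beta, lam=lam,
        gamma=_block_gamma(M, R), c=c, rho=rho, maf=maf, N=N,
    )


def simulate_phenotypes(
    spec: SimulationSpec, g: GenotypeVector | np.ndarray, seed=None
) -> PhenotypeMatrix:
    """Draw the N x M phenotype matrix given genotype counts."""
    counts = np.asarray(getattr(g, "counts", g), dtype=float)
    if counts.size != spec.N:
        spec = SimulationSpec(
            model_id=spec.model_id, M=spec.M, R=spec.R, beta=spec.beta,
            lam=spec.lam, gamma=spec.gamma, c=spec.c, rho=spec.rho,
            maf=spec.maf, N=counts.size,
        )
    rng = _as_rng(seed)
    n, m, r = counts.size, spec.M, spec.R
    sigma_f = (1.0 - spec.rho) * np.eye(r) + spec.rho * np.ones((r, r))
    lf = np.linalg.cholesky(sigma_f)
    f = rng.standard_normal((n, r)) @ lf.T
    eps = rng.standard_normal((n, m))
    y = (
        counts[:, None] * spec.lam[None, :]
        + spec.c * (f @ spec.gamma.T)
        + np.sqrt(1.0 - spec.c2) * eps
    )
    return PhenotypeMatrix(values=y)


def heritability(spec: SimulationSpec) -> dict:
    """Per-phenotype and total heritability of the variant.

    h²(y_j) = var(x) λ_j² / (var(x) λ_j² + 1) with var(x) = 2 maf (1 − maf);
    the total is the sum over phenotypes, with the first-order approximation
    var(x) Σ λ_j² also reported.
    """
    var_x = 2.0 * spec.maf * (1.0 - spec.maf)
    per = var_x * spec.lam**2 / (var_x * spec.lam**2 + 1.0)
    return {
        "var_x": var_x,
        "per_phenotype": per,
        "total": float(per.sum()),
        "total_approx": float(var_x * np.sum(spec.lam**2)),
    }


def simulate_dataset(
    spec: SimulationSpec, seed=None
) -> tuple[GenotypeVector, PhenotypeMatrix]:
    """Genotypes and phenotypes from independent child streams of one seed."""
    ss = (
        seed if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    gs, ps = ss.spawn(2)
    g = simulate_genotypes(spec.N, spec.maf, np.random.default_rng(gs))
    y = simulate_phenotypes(spec, g, np.random.default_rng(ps))
    return g, y
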