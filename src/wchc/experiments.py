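"""Type-I-error and power estimation over the factor-model simulator.

One replicate draws a fresh genotype vector and phenotype matrix from a
:class:`~wchc.simulate.SimulationSpec`, runs the requested methods, and
records their p-values; rejection is counted as p < α uniformly (permutation
p-values can be exactly zero, so p ≤ α and p < α differ only on the
permutation grid).  Replicates receive independent child seeds from a
spawning seed sequence, making the estimates independent of the worker count
when run in parallel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from statsmodels.stats.proportion import proportion_confint

from . import comparators, core
from .clustering import cluster_phenotypes
from .simulate import SimulationSpec, model_config, simulate_dataset

__all__ = [
    "ExperimentConfig",
    "RateEstimate",
    "ALL_METHODS",
    "run_methods_once",
    "simulate_rejection_rates",
    "estimate_type1_error",
    "estimate_power",
    "nominal_ci",
    "PRESETS",
    "run_preset",
]

ALL_METHODS = ("wchc", "wcmulp", "ob", "tates", "shet", "manova", "multiphen")


@dataclass
class ExperimentConfig:
    """Scenario grid plus replication settings for one experiment."""

    scenarios: list[SimulationSpec]
    methods: tuple[str, ...] = ALL_METHODS
    n_replicates: int = 500
    alphas: tuple[float, ...] = (0.01, 0.05)
    B: int = 500  # permutations per replicate (wchc / wcmulp)
    n_mc: int = 2000  # Monte-Carlo draws for the SHet p-value
    seed: int = 0
    n_jobs: int = 1

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        for a in self.alphas:
            if not 0 < a < 1:
                raise ValueError("alpha levels must lie in (0, 1)")
        unknown = [m for m in self.methods if m not in ALL_METHODS]
        if unknown:
            raise ValueError(f"unknown methods {unknown}; choose from {ALL_METHODS}")


@dataclass
class RateEstimate:
    method: str
    scenario: str
    alpha: float
    rate: float
    ci_low: float
    ci_high: float
    n_replicates: int
    n_failed: int = 0


def run_methods_once(
    g, phenotypes, methods: tuple[str, ...], B: int, n_mc: int, seed
) -> dict[str, float]:
    """P-values of the requested methods on one dataset.

    The phenotype clustering for WCHC is computed once from the observed
    phenotypes and reused across that test's permutations.  Failed fits
    (MultiPhen non-convergence) yield NaN.
    """
    ss = (
        seed if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    child = {m: s for m, s in zip(ALL_METHODS, ss.spawn(len(ALL_METHODS)))}
    out: dict[str, float] = {}
    ustats = None
    if {"ob", "tates", "shet"} & set(methods):
        ustats = comparators.univariate_stats(g, phenotypes)
    for m in methods:
        if m == "wchc":
            partition = cluster_phenotypes(phenotypes)
            seed_m = int(child[m].generate_state(1)[0] % (2**31))
            out[m] = core.wchc_test(g, phenotypes, partition, B=B, seed=seed_m).pvalue
        elif m == "wcmulp":
            seed_m = int(child[m].generate_state(1)[0] % (2**31))
            out[m] = core.wcmulp_test(g, phenotypes, B=B, seed=seed_m).pvalue
        elif m == "ob":
            out[m] = comparators.obrien_test(ustats)[1]
        elif m == "tates":
            out[m] = comparators.tates_test(ustats.p, ustats.Corr)
        elif m == "shet":
            seed_m = int(child[m].generate_state(1)[0] % (2**31))
            out[m] = comparators.shet_test(ustats, n_mc=n_mc, seed=seed_m)[1]
        elif m == "manova":
            out[m] = comparators.manova_test(g, phenotypes)[1]
        elif m == "multiphen":
            out[m] = comparators.multiphen_test(g, phenotypes)[1]
    return out


def _scenario_label(spec: SimulationSpec) -> str:
    return (
        f"model{spec.model_id}_M{spec.M}_R{spec.R}_beta{spec.beta:g}_"
        f"c2{spec.c2:g}_rc2{spec.rho_c2:g}"
    )


def _replicate(spec: SimulationSpec, methods, B, n_mc, child_seed):
    data_ss, method_ss = child_seed.spawn(2)
    g, y = simulate_dataset(spec, data_ss)
    return run_methods_once(g, y, methods, B, n_mc, method_ss)


def simulate_rejection_rates(config: ExperimentConfig) -> pd.DataFrame:
    """Rejection rate of each method/scenario/α with exact binomial 95% CI."""
    rows = []
    root = np.random.SeedSequence(config.seed)
    for spec in config.scenarios:
        label = _scenario_label(spec)
        children = root.spawn(config.n_replicates)
        pvals = Parallel(n_jobs=config.n_jobs)(
            delayed(_replicate)(spec, config.methods, config.B, config.n_mc, cs)
            for cs in children
        )
        frame = pd.DataFrame(pvals)
        for m in config.methods:
            p = frame[m].to_numpy()
            ok = np.isfinite(p)
            n_ok = int(ok.sum())
            for a in config.alphas:
                k = int(np.sum(p[ok] < a))
                lo, hi = proportion_confint(k, n_ok, alpha=0.05, method="beta")
                rows.append(
                    RateEstimate(
                        method=m, scenario=label, alpha=a, rate=k / n_ok,
                        ci_low=float(lo), ci_high=float(hi),
                        n_replicates=n_ok, n_failed=int((~ok).sum()),
                    ).__dict__
                )
    df = pd.DataFrame(rows)
    for spec in config.scenarios:
        df.loc[df.scenario == _scenario_label(spec), "beta"] = spec.beta
        df.loc[df.scenario == _scenario_label(spec), "model_id"] = spec.model_id
        df.loc[df.scenario == _scenario_label(spec), "c2"] = spec.c2
    return df


def estimate_type1_error(config: ExperimentConfig) -> pd.DataFrame:
    """Null rejection rates; every scenario must have β = 0."""
    bad = [s for s in config.scenarios if s.beta != 0]
    if bad:
        raise ValueError("type I error scenarios must have beta = 0")
    return simulate_rejection_rates(config)


def estimate_power(config: ExperimentConfig) -> pd.DataFrame:
    """Rejection rates under the alternative; β = 0 rows are null rates."""
    return simulate_rejection_rates(config)


def nominal_ci(alpha: float, n_replicates: int, level: float = 0.95):
    """Normal-approximation CI for an estimated rate at its nominal level."""
    from scipy.stats import norm

    z = norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(alpha * (1.0 - alpha) / n_replicates)
    return alpha - half, alpha + half


def _null_specs(M: int) -> list[SimulationSpec]:
    return [model_config(mid, M=M, beta=0.0) for mid in (1, 2, 4)]


# scenario presets mirroring the study design: null grids for the two
# phenotype counts, and power grids at the published per-model effect sizes
PRESETS = {
    "table1": lambda beta_grid=None: _null_specs(16),
    "table2": lambda beta_grid=None: _null_specs(32),
    "fig1": lambda beta_grid=(0.03, 0.06, 0.09, 0.12): [
        model_config(mid, M=16, beta=b) for mid in range(1, 7) for b in beta_grid
    ],
    "fig2": lambda beta_grid=(0.03, 0.06, 0.09, 0.12): [
        model_config(mid, M=32, beta=b) for mid in range(1, 7) for b in beta_grid
    ],
    "fig3": lambda c2_grid=(0.3, 0.5, 0.7, 0.9): [
        model_config(mid, M=16, beta=b, c2=c2)
        for mid, b in zip(range(1, 7), (0.09, 0.09, 0.08, 0.1, 0.1, 0.07))
        for c2 in c2_grid
    ],
    "fig4": lambda c2_grid=(0.3, 0.5, 0.7, 0.9): [
        model_config(mid, M=32, beta=b, c2=c2)
        for mid, b in zip(range(1, 7), (0.1, 0.09, 0.08, 0.1, 0.1, 0.1))
        for c2 in c2_grid
    ],
}


def run_preset(
    name: str,
    scale: float = 1.0,
    seed: int = 0,
    methods: tuple[str, ...] = ALL_METHODS,
    n_jobs: int = 1,
) -> pd.DataFrame:
    """Run a named scenario preset, scaling replicates/permutations by ``scale``.

    Full scale is 2,000 replicates x 2,000 permutations for the null tables
    and 1,000 x 1,000 for the power figures.
    """
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    scenarios = PRESETS[name]()
    null_table = name in ("table1", "table2")
    base = 2000 if null_table else 1000
    n_rep = max(1, int(round(base * scale)))
    B = max(1, int(round(base * scale)))
    config = ExperimentConfig(
        scenarios=scenarios,
        methods=methods,
        n_replicates=n_rep,
        alphas=(0.01, 0.05) if null_table else (0.05,),
        B=B,
        seed=seed,
        n_jobs=n_jobs,
    )
    return simulate_rejection_rates(config)
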