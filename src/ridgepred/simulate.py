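"""Genotype/phenotype simulator for the additive quantitative-trait model.

One cohort (one "run") draws a single genotype matrix and derives every
phenotype from it:

    f_p  ~ U(0.05, 0.95)                    per-SNP allele frequency
    g_ip ~ Binom(2, f_p)                    independent biallelic dosages
    x_ip = (g_ip - 2 f_p) / sqrt(2 f_p (1 - f_p))
    y_i  = Σ_{p=1..C} x_ip β_p + ε_i,   β_p ~ N(0, σ²_β),  ε_i ~ N(0, σ²_ε)

so only common variants exist, SNPs are mutually independent (no linkage
disequilibrium), and the first C = max(1, round(f_C·P)) SNPs of each P-level
submatrix are causal. The genetic score and the noise are rescaled — after
centering and orthogonalizing ε to the score — so that the *sample*
heritability var(g)/var(y) equals the target h² exactly, which keeps
downstream accuracy checks sharp.

A factor grid (sample size N, SNP count P, causal fraction f_C,
heritability h²) is evaluated on nested slices of the one cohort: smaller
P-levels are leading columns of the big matrix, the training set is the
first N rows and the test set the next ⌊1.1N⌋ - N rows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["SimConfig", "SimulatedCohort", "draw_genotypes",
           "build_phenotypes", "split_train_test", "simulate_cohort"]

_TABLE_N = (200, 500, 1_000, 2_000, 5_000, 10_000, 20_000)
_TABLE_P = (100, 200, 500, 1_000, 2_000, 5_000, 10_000, 20_000,
            50_000, 100_000, 200_000, 500_000)


def _fc_levels(n_levels: int = 37) -> tuple[float, ...]:
    """Log-uniform causal fractions from 0.1% to 100%."""
    return tuple(np.logspace(-3.0, 0.0, n_levels))


def _h2_levels() -> tuple[float, ...]:
    """Heritabilities 5%, 10%, ..., 100%."""
    return tuple(np.round(np.arange(1, 21) * 0.05, 2))


@dataclass
class SimConfig:
    """Factor levels and run count of a simulation study."""

    N_list: tuple = _TABLE_N
    P_list: tuple = _TABLE_P
    fC_list: tuple = field(default_factory=_fc_levels)
    h2_list: tuple = field(default_factory=_h2_levels)
    R: int = 21
    N_max: int | None = None
    P_max: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.N_list = tuple(int(n) for n in self.N_list)
        self.P_list = tuple(int(p) for p in self.P_list)
        self.fC_list = tuple(float(f) for f in self.fC_list)
        self.h2_list = tuple(float(h) for h in self.h2_list)
        if self.N_max is None:
            self.N_max = math.floor(1.1 * max(self.N_list))
        if self.P_max is None:
            self.P_max = max(self.P_list)
        if math.floor(1.1 * max(self.N_list)) > self.N_max:
            raise ValueError("N_max too small for the largest N level "
                             "(needs ⌊1.1·max N⌋ rows)")
        if max(self.P_list) > self.P_max:
            raise ValueError("P_max smaller than the largest P level")
        if not all(0 < f <= 1 for f in self.fC_list):
            raise ValueError("causal fractions must lie in (0, 1]")
        if not all(0 < h <= 1 for h in self.h2_list):
            raise ValueError("heritabilities must lie in (0, 1]")
        if self.R < 1:
            raise ValueError("run count R must be at least 1")

    @property
    def n_scenarios(self) -> int:
        return (len(self.N_list) * len(self.P_list)
                * len(self.fC_list) * len(self.h2_list))

    @property
    def n_scenario_runs(self) -> int:
        return self.n_scenarios * self.R

    @classmethod
    def table1(cls, seed: int = 0) -> "SimConfig":
        """The full published factor grid (62,160 scenarios, R = 21)."""
        return cls(seed=seed)

    @classmethod
    def desk_scale(cls, seed: int = 0) -> "SimConfig":
        """The full grid trimmed to N ≤ 2,000 and P ≤ 5,000."""
        return cls(N_list=tuple(n for n in _TABLE_N if n <= 2_000),
                   P_list=tuple(p for p in _TABLE_P if p <= 5_000),
                   seed=seed)

    @classmethod
    def smoke(cls, seed: int = 0, R: int = 21) -> "SimConfig":
        """The N = P = 2,000, f_C = 1%, h² = 0.5 single-cell study."""
        return cls(N_list=(2_000,), P_list=(2_000,), fC_list=(0.01,),
                   h2_list=(0.5,), R=R, seed=seed)

    def run_seeds(self) -> list[np.random.SeedSequence]:
        return np.random.SeedSequence(self.seed).spawn(self.R)


def draw_genotypes(N_total: int, P: int, seed) -> tuple[np.ndarray, np.ndarray]:
    """Draw a genotype matrix G (N_total×P, int8 counts) and frequencies f."""
    if N_total < 1 or P < 1:
        raise ValueError("N_total and P must be positive")
    rng = np.random.default_rng(seed)
    f = rng.uniform(0.05, 0.95, size=P)
    G = rng.binomial(2, f, size=(N_total, P)).astype(np.int8)
    return G, f


def true_frequency_standardize(G: np.ndarray, f: np.ndarray) -> np.ndarray:
    """x_ip = (g_ip - 2f_p)/sqrt(2f_p(1-f_p)) with the generating frequencies."""
    return (G.astype(float) - 2.0 * f) / np.sqrt(2.0 * f * (1.0 - f))


def build_phenotypes(X: np.ndarray, P_level: int, fC: float, h2: float,
                     seed) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate a trait on the first C SNPs of the P_level-column submatrix.

    Returns ``(y, causal_mask, beta)`` where ``beta`` is on the scale of the
    returned phenotype (genetic score sample variance is exactly h² and the
    noise exactly 1 - h², with the noise orthogonalized to the score).
    """
    X = np.asarray(X, dtype=float)
    if h2 <= 0 or h2 > 1:
        raise ValueError(f"h² must lie in (0, 1], got {h2!r}")
    if P_level > X.shape[1]:
        raise ValueError("P_level exceeds available SNPs")
    C = max(1, round(fC * P_level))
    if C > P_level:
        raise ValueError("causal count exceeds P_level")
    rng = np.random.default_rng(seed)
    n = X.shape[0]

    beta = rng.standard_normal(C)
    g = X[:, :C] @ beta
    g = g - g.mean()
    g_var = g @ g / (n - 1)
    if g_var == 0:
        raise ValueError("degenerate genetic score (zero variance)")
    scale_g = math.sqrt(h2 / g_var)
    g *= scale_g
    beta = beta * scale_g

    if h2 == 1.0:
        eps = np.zeros(n)
    else:
        eps = rng.standard_normal(n)
        eps = eps - eps.mean()
        eps = eps - (g @ eps) / (g @ g) * g   # exact orthogonality to the score
        eps *= math.sqrt((1.0 - h2) / (eps @ eps / (n - 1)))

    mask = np.zeros(X.shape[1], dtype=bool)
    mask[:C] = True
    return g + eps, mask, beta


def split_train_test(N: int, cohort_size: int) -> tuple[np.ndarray, np.ndarray]:
    """Training rows [0, N) and test rows [N, ⌊1.1N⌋) of a cohort slice."""
    if N < 10:
        raise ValueError("training size must be at least 10")
    n_total = math.floor(1.1 * N)
    if n_total > cohort_size:
        raise ValueError(f"cohort of {cohort_size} rows cannot supply "
                         f"⌊1.1N⌋ = {n_total} individuals")
    return np.arange(N), np.arange(N, n_total)


@dataclass
class SimulatedCohort:
    """One run's genotypes plus the phenotype array over the factor grid.

    ``phenotypes`` is indexed [individual, P-level, f_C-level, h²-level];
    ``betas[(iP, ifC, ih2)]`` holds the causal effects (phenotype scale) and
    ``causal_counts[iP, ifC]`` the causal SNP count of each cell.
    """

    config: SimConfig
    G: np.ndarray
    f: np.ndarray
    X: np.ndarray
    phenotypes: np.ndarray
    betas: dict
    causal_counts: np.ndarray


def simulate_cohort(config: SimConfig, seed) -> SimulatedCohort:
    """Generate one run: a single genotype draw and all grid phenotypes."""
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    geno_seed, pheno_seed = root.spawn(2)
    G, f = draw_genotypes(config.N_max, config.P_max, geno_seed)
    X = true_frequency_standardize(G, f)

    nP, nF, nH = len(config.P_list), len(config.fC_list), len(config.h2_list)
    phen = np.empty((config.N_max, nP, nF, nH))
    betas: dict = {}
    causal_counts = np.zeros((nP, nF), dtype=int)
    cell_seeds = iter(pheno_seed.spawn(nP * nF * nH))
    for iP, P in enumerate(config.P_list):
        for iF, fC in enumerate(config.fC_list):
            causal_counts[iP, iF] = max(1, round(fC * P))
            for iH, h2 in enumerate(config.h2_list):
                y, mask, beta = build_phenotypes(X[:, :P], P, fC, h2,
                                                 next(cell_seeds))
                phen[:, iP, iF, iH] = y
                betas[(iP, iF, iH)] = beta
    return SimulatedCohort(config, G, f, X, phen, betas, causal_counts)
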