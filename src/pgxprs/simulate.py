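"""Synthetic two-arm PGx study generator.

The generator emulates the structure of a pharmacogenomics GWAS built on
trial genotypes: LD-structured haplotypes partitioned into blocks, a
block-level mixture distribution of paired (prognostic, predictive)
effect sizes, fixed-heritability two-arm phenotypes, and a larger
"disease GWAS" cohort synthesized by random mating.

Genotypes: within each block, haplotype alleles come from thresholding a
latent AR(1) Gaussian process (decay parameter `ld_decay`), giving LD that
decays with distance; blocks are mutually independent. MAFs are drawn
uniformly on [0.05, 0.5]. Dosage is the sum of two haplotypes.

Effects (per block k): pi_k ~ Beta(P(causal), 1 - P(causal)) makes the
causal fraction vary across blocks while its genome-wide mean equals
P(causal); each SNP is causal with probability pi_k, and causal pairs
(beta_j, alpha_j) ~ MVN(0, Sigma_k) with Sigma_k diagonal (psi, xi) and
off-diagonal rho_k sqrt(psi xi), rho_k ~ Uniform(0, 1). In
"separate-effects" mode a random half of the causal variants keeps only
the prognostic effect and the other half only the predictive effect.

Phenotypes: Y = X 1 + beta_T T + G beta + (G x T) alpha + eps with
G standardized; the residual variance sigma^2 is calibrated so that the
treatment-arm heritability var(sum (beta+alpha) G) / (var(.) + sigma^2)
equals the configured H^2. The disease cohort uses Y = X 1 + G beta + eps
with the same sigma^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import PGxCohort, SNP_META_COLUMNS
from .ld import LDBlockSet

#: base-pair spacing between adjacent simulated SNPs
SNP_SPACING_BP = 2000


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic benchmark."""

    m: int = 5000
    n_pgx: int = 4000
    n_test: int = 1000
    n_disease: int = 20000
    n_ref: int = 500
    p_causal: float = 0.01
    h2: float = 0.3
    psi_xi_ratio: float = 1.0
    beta_t: float = 0.0
    separate_effects: bool = False
    mu_t: float = 0.5
    n_covariates: int = 5
    block_size: int = 50
    ld_decay: float = 0.9
    maf_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.p_causal < 1:
            raise ValueError("P(causal) must lie in [0, 1)")
        if not 0 < self.h2 < 1:
            raise ValueError("heritability must lie in (0, 1)")
        if min(self.m, self.n_pgx, self.n_disease) <= 0:
            raise ValueError("sizes must be positive")


@dataclass
class SimGenotypes:
    """Haplotypes (2n x m, 0/1) plus block structure and SNP metadata."""

    haplotypes: np.ndarray
    block_bounds: list[tuple[int, int]]  # [start, end) column ranges
    snp_meta: pd.DataFrame
    maf: np.ndarray

    @property
    def dosages(self) -> np.ndarray:
        return (self.haplotypes[0::2] + self.haplotypes[1::2]).astype(float)

    @property
    def n(self) -> int:
        return self.haplotypes.shape[0] // 2

    @property
    def m(self) -> int:
        return self.haplotypes.shape[1]


@dataclass
class TrueEffects:
    beta: np.ndarray
    alpha: np.ndarray
    causal: np.ndarray
    rho_k: np.ndarray
    sigma2: float | None = None

    @property
    def m(self) -> int:
        return self.beta.size


def simulate_genotypes(m: int, n: int, block_size: int = 50, ld_decay: float = 0.9,
                       maf_range: tuple[float, float] = (0.05, 0.5),
                       rng: np.random.Generator | int = 0) -> SimGenotypes:
    """LD-structured haplotypes for n diploid individuals and m SNPs."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    maf = rng.uniform(*maf_range, size=m)
    thresh = stats.norm.ppf(maf)
    n_hap = 2 * n
    bounds = []
    start = 0
    while start < m:
        end = min(start + block_size, m)
        bounds.append((start, end))
        start = end
    if ld_decay == 0:
        z = rng.standard_normal((n_hap, m))
    else:
        z = np.empty((n_hap, m))
        scale = np.sqrt(1.0 - ld_decay**2)
        for s, e in bounds:
            z[:, s] = rng.standard_normal(n_hap)
            for j in range(s + 1, e):
                z[:, j] = ld_decay * z[:, j - 1] + scale * rng.standard_normal(n_hap)
    hap = (z < thresh).astype(np.int8)
    meta = pd.DataFrame({
        "chrom": "1",
        "pos": SNP_SPACING_BP * (1 + np.arange(m)),
        "ref": "A", "alt": "C",
        "maf": maf,
    })[SNP_META_COLUMNS]
    return SimGenotypes(haplotypes=hap, block_bounds=bounds, snp_meta=meta, maf=maf)


def block_set(geno: SimGenotypes) -> LDBlockSet:
    rows = [("1", int(geno.snp_meta["pos"].iloc[s]),
             int(geno.snp_meta["pos"].iloc[e - 1]) + 1)
            for s, e in geno.block_bounds]
    return LDBlockSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]),
                      provenance="simulated")


def expand_random_mating(geno: SimGenotypes, target_n: int,
                         rng: np.random.Generator | int = 0) -> SimGenotypes:
    """Offspring cohort: each child gets one whole-block haplotype from each
    of two distinct random parents (blocks recombine freely, within-block
    phase is preserved, so allele frequencies and within-block LD carry over).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n = geno.n
    if n < 2:
        raise ValueError("need at least 2 parents for random mating")
    if target_n < n:
        raise ValueError("target_n must be >= current n")
    p1 = rng.integers(0, n, size=target_n)
    p2 = rng.integers(0, n, size=target_n)
    clash = p1 == p2
    while clash.any():
        p2[clash] = rng.integers(0, n, size=int(clash.sum()))
        clash = p1 == p2
    m = geno.m
    child = np.empty((2 * target_n, m), dtype=np.int8)
    n_blocks = len(geno.block_bounds)
    pick1 = rng.integers(0, 2, size=(target_n, n_blocks))
    pick2 = rng.integers(0, 2, size=(target_n, n_blocks))
    H = geno.haplotypes
    for bi, (s, e) in enumerate(geno.block_bounds):
        child[0::2, s:e] = H[2 * p1 + pick1[:, bi]][:, s:e]
        child[1::2, s:e] = H[2 * p2 + pick2[:, bi]][:, s:e]
    return SimGenotypes(haplotypes=child, block_bounds=geno.block_bounds,
                        snp_meta=geno.snp_meta.copy(), maf=geno.maf)


def draw_effects(config: SimConfig, block_bounds: list[tuple[int, int]],
                 rng: np.random.Generator | int = 0) -> TrueEffects:
    """Block-wise mixture of bivariate normal effect sizes."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    m = config.m
    p = config.p_causal
    beta = np.zeros(m)
    alpha = np.zeros(m)
    causal = np.zeros(m, dtype=bool)
    rho_k = np.zeros(len(block_bounds))
    xi = 1.0
    psi = config.psi_xi_ratio * xi
    for k, (s, e) in enumerate(block_bounds):
        rho_k[k] = rng.uniform(0.0, 1.0)
        if p == 0:
            continue
        pi_k = rng.beta(p, 1.0 - p)
        is_causal = rng.random(e - s) < pi_k
        idx = np.flatnonzero(is_causal) + s
        if idx.size == 0:
            continue
        causal[idx] = True
        cov = np.array([[psi, rho_k[k] * np.sqrt(psi * xi)],
                        [rho_k[k] * np.sqrt(psi * xi), xi]])
        draws = rng.multivariate_normal(np.zeros(2), cov, size=idx.size,
                                        method="cholesky")
        beta[idx] = draws[:, 0]
        alpha[idx] = draws[:, 1]
    if config.separate_effects and causal.any():
        idx = np.flatnonzero(causal)
        half = rng.permutation(idx.size) < idx.size // 2
        alpha[idx[half]] = 0.0    # prognostic-only half
        beta[idx[~half]] = 0.0    # predictive-only half
    return TrueEffects(beta=beta, alpha=alpha, causal=causal, rho_k=rho_k)


def _standardize_columns(g: np.ndarray) -> np.ndarray:
    sd = g.std(axis=0)
    sd[sd == 0] = 1.0
    return (g - g.mean(axis=0)) / sd


def generate_phenotype(G_std: np.ndarray, T: np.ndarray | None, X: np.ndarray,
                       effects: TrueEffects, h2: float | None, beta_t: float = 0.0,
                       sigma2: float | None = None,
                       rng: np.random.Generator | int = 0
                       ) -> tuple[np.ndarray, float]:
    """Two-arm (or disease, T=None) phenotype with calibrated residual variance.

    When ``sigma2`` is not given, it is solved from the treatment-arm
    heritability identity using the empirical variance of the combined
    genetic component among treated subjects; scaling all effects leaves
    the realized heritability unchanged.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n = G_std.shape[0]
    if sigma2 is None:
        if h2 is None:
            sigma2 = 1.0
        else:
            full = G_std @ (effects.beta + effects.alpha)
            treated = full if T is None else full[np.asarray(T) == 1]
            if treated.size == 0:
                treated = full
            gvar = float(np.var(treated))
            if not np.isfinite(gvar) or gvar == 0:
                raise ValueError("all-zero genetic effects: heritability undefined")
            sigma2 = gvar * (1.0 - h2) / h2
    eps = rng.normal(0.0, np.sqrt(sigma2), size=n)
    y = X @ np.ones(X.shape[1]) + G_std @ effects.beta + eps
    if T is not None:
        T = np.asarray(T, dtype=float)
        y = y + beta_t * T + (G_std * T[:, None]) @ effects.alpha
    return y, float(sigma2)


@dataclass
class SimScenario:
    """One benchmark replicate: cohorts, truth and LD structure."""

    train: PGxCohort
    test: PGxCohort
    disease: PGxCohort
    ref_G: np.ndarray
    effects: TrueEffects
    blocks: LDBlockSet
    block_bounds: list[tuple[int, int]]
    config: SimConfig
    sigma2: float


def make_benchmark_scenario(config: SimConfig,
                            rng: np.random.Generator | int | None = None
                            ) -> SimScenario:
    """Generate one train/test/disease/reference replicate of the study design."""
    if rng is None:
        rng = config.seed
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n_train = config.n_pgx - config.n_test
    if n_train <= 0:
        raise ValueError("n_pgx must exceed n_test")

    geno = simulate_genotypes(config.m, config.n_pgx, config.block_size,
                              config.ld_decay, config.maf_range, rng)
    effects = draw_effects(config, geno.block_bounds, rng)
    if config.p_causal > 0:
        # condition on a non-null architecture: sigma^2 calibration needs
        # at least one causal variant
        attempts = 0
        while not effects.causal.any():
            attempts += 1
            if attempts > 200:
                raise RuntimeError("could not draw a non-null effect configuration")
            effects = draw_effects(config, geno.block_bounds, rng)

    G = geno.dosages
    G_std = _standardize_columns(G)
    T = (rng.random(config.n_pgx) < config.mu_t).astype(float)
    X = rng.standard_normal((config.n_pgx, config.n_covariates))
    y, sigma2 = generate_phenotype(G_std, T, X, effects, config.h2,
                                   config.beta_t, rng=rng)
    effects.sigma2 = sigma2

    perm = rng.permutation(config.n_pgx)
    tr, te = perm[:n_train], perm[n_train:]
    meta = geno.snp_meta
    train = PGxCohort(Y=y[tr], T=T[tr], X=X[tr], G=G[tr], snp_meta=meta.copy())
    test = PGxCohort(Y=y[te], T=T[te], X=X[te], G=G[te], snp_meta=meta.copy())

    dis_geno = expand_random_mating(geno, config.n_disease, rng)
    G_dis = _standardize_columns(dis_geno.dosages)
    X_dis = rng.standard_normal((config.n_disease, config.n_covariates))
    y_dis, _ = generate_phenotype(G_dis, None, X_dis, effects, config.h2,
                                  sigma2=sigma2, rng=rng)
    disease = PGxCohort(Y=y_dis, T=np.zeros(config.n_disease), X=X_dis,
                        G=dis_geno.dosages, snp_meta=meta.copy())

    ref = expand_random_mating(geno, config.n_pgx, rng)
    ref_G = ref.dosages[:config.n_ref]

    return SimScenario(train=train, test=test, disease=disease, ref_G=ref_G,
                       effects=effects, blocks=block_set(geno),
                       block_bounds=geno.block_bounds, config=config,
                       sigma2=sigma2)
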