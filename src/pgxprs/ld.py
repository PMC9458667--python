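"""LD blocks, reference-panel correlation matrices, and clumping.

A genome is partitioned into approximately independent LD blocks
(half-open 1-based intervals, as produced by ldetect-style pipelines).
Within each block the SNP correlation matrix Sigma comes from a reference
panel, and the joint-design correlation

    D = cor([G, G x T]) = [[Sigma, sqrt(mu_T) Sigma],
                           [sqrt(mu_T) Sigma, Sigma]]

follows from standardized genotypes and randomized treatment (T independent
of G): for the standardized interaction column G_j T / sqrt(mu_T),
cor(G_i, G_j T / sqrt(mu_T)) = sqrt(mu_T) Sigma_ij and
cor(G_i T, G_j T) / mu_T = Sigma_ij. This construction is validated against
an empirical cor([G, GxT]) Monte-Carlo oracle in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: ridge ladder tried in order until D is positive definite
RIDGE_LADDER = (0.0, 1e-3, 1e-2, 1e-1)


@dataclass
class LDBlockSet:
    """Ordered (chrom, start, end) half-open intervals on 1-based coordinates."""

    intervals: pd.DataFrame  # columns chrom, start, end
    provenance: str = ""

    def __post_init__(self) -> None:
        df = self.intervals
        for col in ("chrom", "start", "end"):
            if col not in df.columns:
                raise ValueError(f"block table missing column {col!r}")
        df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
        for _, grp in df.groupby("chrom"):
            if (grp["start"].values[1:] < grp["end"].values[:-1]).any():
                raise ValueError("overlapping LD blocks within a chromosome")
        self.intervals = df

    def __len__(self) -> int:
        return len(self.intervals)

    @classmethod
    def read(cls, path: str | Path) -> "LDBlockSet":
        df = pd.read_csv(path, sep="\t", comment="#",
                         names=["chrom", "start", "end"], dtype={"chrom": str})
        return cls(df, provenance=str(path))

    def write(self, path: str | Path) -> None:
        self.intervals.to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def uniform(cls, snp_meta: pd.DataFrame, block_size: int) -> "LDBlockSet":
        """Blocks of `block_size` consecutive SNPs (for simulated data)."""
        rows = []
        for chrom, grp in snp_meta.groupby("chrom", sort=False):
            pos = np.sort(grp["pos"].values)
            for i in range(0, len(pos), block_size):
                chunk = pos[i:i + block_size]
                rows.append((chrom, int(chunk[0]), int(chunk[-1]) + 1))
        return cls(pd.DataFrame(rows, columns=["chrom", "start", "end"]),
                   provenance=f"uniform-{block_size}")


def assign_blocks(snp_meta: pd.DataFrame, blocks: LDBlockSet) -> np.ndarray:
    """Block index for every SNP; start is inside, end is outside (half-open).

    SNPs falling outside all intervals of their chromosome are collected in a
    per-chromosome catch-all block appended after the real ones.
    """
    n_real = len(blocks)
    out = np.full(len(snp_meta), -1, dtype=int)
    iv = blocks.intervals
    for bi, row in iv.iterrows():
        mask = ((snp_meta["chrom"].astype(str) == str(row["chrom"]))
                & (snp_meta["pos"] >= row["start"]) & (snp_meta["pos"] < row["end"]))
        out[np.asarray(mask)] = bi
    # catch-all residual blocks, one per chromosome with orphans
    orphan_chroms = pd.unique(snp_meta["chrom"][out == -1])
    for k, chrom in enumerate(orphan_chroms):
        mask = (out == -1) & np.asarray(snp_meta["chrom"] == chrom)
        out[mask] = n_real + k
    return out


@dataclass
class JointLD:
    """Per-block Sigma and joint-design D, block-aligned with a SummaryStats."""

    sigma: np.ndarray
    D: np.ndarray
    mu_t: float
    ridge: float = 0.0
    dropped: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def ld_matrix(ref_genotypes: np.ndarray, drop_monomorphic: bool = True
              ) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation of reference dosages for one block.

    Returns (Sigma, kept_idx). Monomorphic panel SNPs cannot be correlated;
    they are dropped and flagged via kept_idx.
    """
    g = np.asarray(ref_genotypes, dtype=float)
    if g.shape[0] < 2:
        raise ValueError("need at least 2 reference samples for LD")
    sd = g.std(axis=0)
    kept = np.flatnonzero(sd > 0)
    if kept.size < g.shape[1]:
        if not drop_monomorphic:
            raise ValueError("monomorphic SNP in reference panel")
        logger.warning("ld_matrix: dropped %d monomorphic panel SNP(s)",
                       g.shape[1] - kept.size)
    z = (g[:, kept] - g[:, kept].mean(axis=0)) / sd[kept]
    sigma = z.T @ z / g.shape[0]
    np.fill_diagonal(sigma, 1.0)
    return np.clip(sigma, -1.0, 1.0), kept


def _is_pd(a: np.ndarray) -> bool:
    try:
        np.linalg.cholesky(a)
        return True
    except np.linalg.LinAlgError:
        return False


def build_D(sigma: np.ndarray, mu_t: float,
            ridge_ladder: tuple[float, ...] = RIDGE_LADDER) -> JointLD:
    """Joint-design correlation D from a block Sigma and the treatment fraction.

    D is ridge-regularized as (1 - eps) D + eps I with the smallest eps from
    the ladder that makes it positive definite (reference panels are often
    smaller than the block, so raw D can be rank deficient).
    """
    if not 0 < mu_t < 1:
        raise ValueError("mu_t must lie strictly in (0, 1)")
    sigma = np.asarray(sigma, dtype=float)
    c = np.sqrt(mu_t)
    D = np.block([[sigma, c * sigma], [c * sigma, sigma]])
    for eps in ridge_ladder:
        Dr = (1 - eps) * D + eps * np.eye(D.shape[0])
        if _is_pd(Dr):
            return JointLD(sigma=sigma, D=Dr, mu_t=mu_t, ridge=eps)
    raise np.linalg.LinAlgError("joint LD matrix not positive definite after ridge ladder")


def clump(snp_meta: pd.DataFrame, p_values: np.ndarray, sigma: np.ndarray,
          window_kb: float = 250.0, r2_threshold: float = 0.01) -> np.ndarray:
    """Greedy LD clumping; returns the sorted indices of kept SNPs.

    SNPs are visited by ascending p-value (ties broken by position then
    alphabetical alleles, for reproducibility); each kept index SNP removes
    all unprocessed SNPs on the same chromosome within ``window_kb`` kb whose
    squared correlation with it exceeds ``r2_threshold``.
    """
    m = len(snp_meta)
    p_values = np.asarray(p_values, dtype=float)
    if sigma.shape != (m, m):
        raise ValueError("sigma must be m x m for the clumping SNP set")
    order = sorted(
        range(m),
        key=lambda j: (p_values[j], snp_meta["pos"].iloc[j],
                       str(snp_meta["ref"].iloc[j]), str(snp_meta["alt"].iloc[j])),
    )
    pos = snp_meta["pos"].to_numpy()
    chrom = snp_meta["chrom"].astype(str).to_numpy()
    window = window_kb * 1000.0
    alive = np.ones(m, dtype=bool)
    kept = []
    for j in order:
        if not alive[j]:
            continue
        kept.append(j)
        alive[j] = False
        near = alive & (chrom == chrom[j]) & (np.abs(pos - pos[j]) <= window)
        near &= sigma[j] ** 2 > r2_threshold
        alive[near] = False
    return np.sort(np.asarray(kept, dtype=int))
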