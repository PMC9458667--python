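"""Summary-statistics scoring baselines: unadjusted weights and C+T.

``prs_pgx_unadj`` keeps every SNP with its marginal prognostic and
predictive estimates as weights. ``prs_pgx_ct`` applies LD clumping
(250 kb window, r^2 > 0.01 by default) followed by thresholding on the
2-df joint-test p-value: SNPs not passing the threshold have both effects
shrunk to zero. ``prs_dis_ct`` is the disease-PRS baseline: the same C+T
machinery on main-effect (1-df) disease GWAS statistics, with all
predictive weights identically zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import EffectEstimates, PGxCohort, SummaryStats
from .ld import LDBlockSet, assign_blocks, clump

logger = logging.getLogger(__name__)

#: p-value grid of the C+T thresholding step
DEFAULT_PT_GRID = (5e-08, 1e-07, 1e-06, 1e-05, 1e-04, 0.001, 0.01, 0.1, 1.0)


@dataclass
class CTConfig:
    """Clumping + thresholding configuration."""

    pt_grid: tuple[float, ...] = DEFAULT_PT_GRID
    window_kb: float = 250.0
    r2_threshold: float = 0.01

    def __post_init__(self) -> None:
        if any(not (0 < p <= 1) for p in self.pt_grid):
            raise ValueError("p-value grid entries must lie in (0, 1]")


def prs_pgx_unadj(ss: SummaryStats) -> EffectEstimates:
    """Identity weights: every SNP enters with (beta_hat, alpha_hat)."""
    return EffectEstimates(
        snp_meta=ss.table, beta_est=ss.beta_hat, alpha_est=ss.alpha_hat,
        method="PRS-PGx-Unadj", mu_t=ss.mu_t,
    )


def _clump_blockwise(table: pd.DataFrame, p: np.ndarray,
                     sigma_blocks: list[np.ndarray], block_idx: np.ndarray,
                     config: CTConfig) -> np.ndarray:
    """Clump within each LD block (cross-block r^2 treated as zero)."""
    kept = []
    for bi, sigma in enumerate(sigma_blocks):
        rows = np.flatnonzero(block_idx == bi)
        if rows.size == 0:
            continue
        local = clump(table.iloc[rows].reset_index(drop=True), p[rows], sigma,
                      window_kb=config.window_kb, r2_threshold=config.r2_threshold)
        kept.append(rows[local])
    return np.sort(np.concatenate(kept)) if kept else np.array([], dtype=int)


def prs_pgx_ct(ss: SummaryStats, sigma_blocks: list[np.ndarray],
               block_idx: np.ndarray, config: CTConfig, p_t: float
               ) -> EffectEstimates:
    """Clumping + 2-df p-value thresholding on PGx summary statistics."""
    kept = _clump_blockwise(ss.table, ss.p2df, sigma_blocks, block_idx, config)
    selected = kept[ss.p2df[kept] <= p_t]
    if selected.size == 0:
        warnings.warn(f"PRS-PGx-CT: no SNP passes P_T={p_t:g}; returning zero weights")
    beta = np.zeros(ss.m)
    alpha = np.zeros(ss.m)
    beta[selected] = ss.beta_hat[selected]
    alpha[selected] = ss.alpha_hat[selected]
    return EffectEstimates(
        snp_meta=ss.table, beta_est=beta, alpha_est=alpha,
        method="PRS-PGx-CT", mu_t=ss.mu_t,
        params={"p_t": p_t, "n_selected": int(selected.size)},
    )


def prs_dis_ct(disease_ss: pd.DataFrame, sigma_blocks: list[np.ndarray],
               block_idx: np.ndarray, config: CTConfig, p_t: float
               ) -> EffectEstimates:
    """Disease C+T baseline: main effects only, predictive weights all zero.

    ``disease_ss`` must carry columns beta_hat and p1df (from
    :func:`pgxprs.io.compute_disease_summary_stats`).
    """
    p = np.asarray(disease_ss["p1df"], dtype=float)
    kept = _clump_blockwise(disease_ss, p, sigma_blocks, block_idx, config)
    selected = kept[p[kept] <= p_t]
    if selected.size == 0:
        warnings.warn(f"PRS-Dis-CT: no SNP passes P_T={p_t:g}; returning zero weights")
    beta = np.zeros(len(disease_ss))
    beta[selected] = np.asarray(disease_ss["beta_hat"], dtype=float)[selected]
    return EffectEstimates(
        snp_meta=disease_ss, beta_est=beta, alpha_est=np.zeros(len(disease_ss)),
        method="PRS-Dis-CT", mu_t=1.0,
        params={"p_t": p_t, "n_selected": int(selected.size)},
    )


def select_threshold(ss_train: SummaryStats, validation_cohort: PGxCohort,
                     sigma_blocks: list[np.ndarray], block_idx: np.ndarray,
                     config: CTConfig, disease_ss: pd.DataFrame | None = None
                     ) -> tuple[float, EffectEstimates]:
    """Pick the grid threshold maximizing two-arm R^2 on a validation cohort.

    Ties are resolved toward the smaller (sparser) threshold. When
    ``disease_ss`` is given the search runs over the disease baseline instead.
    """
    from .evaluate import two_arm_r2

    if np.std(validation_cohort.Y) == 0:
        raise ValueError("validation cohort has constant response")
    best = None
    for p_t in sorted(config.pt_grid):
        if disease_ss is not None:
            est = prs_dis_ct(disease_ss, sigma_blocks, block_idx, config, p_t)
        else:
            est = prs_pgx_ct(ss_train, sigma_blocks, block_idx, config, p_t)
        r2 = two_arm_r2(validation_cohort, est)
        if best is None or r2 > best[0] + 1e-12:
            best = (r2, p_t, est)
    return best[1], best[2]
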