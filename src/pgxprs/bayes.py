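"""Summary-statistics Gibbs sampler with a bivariate global-local
continuous shrinkage prior (PRS-PGx-Bayes).

Model, per LD block with m SNPs and joint design correlation D
(2m x 2m, SNP-major order [beta_1..beta_m, alpha_1..alpha_m]):

    b | sigma^2, phi, {M_j} ~ MVN(0, (sigma^2/n) Omega),   Omega = phi * M,
    M_j = [[psi_j, rho_j sqrt(psi_j xi_j)], [., xi_j]] ~ IW(B_j, 2v + 1),
    B_j = 4v diag(delta_j, lambda_j),
    delta_j ~ Gamma(b1, 1),  lambda_j ~ Gamma(b2, 1),
    p(sigma^2) ∝ 1/sigma^2.

The half-t hierarchy implies the marginals psi_j ~ invGamma(v, 2v delta_j),
xi_j ~ invGamma(v, 2v lambda_j) and p(rho_j) ∝ (1 - rho_j^2)^v, so the
per-SNP variances and the correlation are controlled separately. phi is a
global scale shared by all SNPs (grid-tuned, not sampled).

Full conditionals (validated against a brute-force individual-level Gibbs
sampler in the test suite):

  b       ~ MVN((D + Omega^-1)^-1 b_hat, (sigma^2/n)(D + Omega^-1)^-1)
  sigma^2 ~ invGamma((n + 2m)/2,
                     (n/2) max(1 - 2 b'b_hat + b'Db, 0) + (n/2) b'Omega^-1 b)
  M_j     ~ IW(B_j + (n/(sigma^2 phi)) b_j b_j', 2v + 2),
            then capped so that phi*psi_j <= rho_cap and phi*xi_j <= rho_cap
            (rho_j preserved, off-diagonal recomputed)
  delta_j ~ Gamma(b1 + (2v+1)/2, 1 + 2v (M_j^-1)_11),
  lambda_j~ Gamma(b2 + (2v+1)/2, 1 + 2v (M_j^-1)_22).

Blocks are sampled independently with RNG streams derived from
(seed, block index), so results do not depend on execution order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla

from .io import EffectEstimates, SummaryStats

logger = logging.getLogger(__name__)


class GibbsDivergenceError(RuntimeError):
    """Raised when the residual-variance chain overflows in a block."""


@dataclass
class BayesHyper:
    """Hyperparameters and chain controls for the Gibbs sampler."""

    phi_grid: tuple[float, ...] = (1e-4, 1e-2, 1e-1, 1.0)
    v_grid: tuple[float, ...] = (2.0, 5.0, 10.0)
    b1: float = 0.5
    b2: float = 0.5
    rho_cap: float = 1.0
    iterations: int = 1000
    burn_in: int = 500
    thinning: int = 1
    seed: int = 0
    tuning_iterations: int | None = None
    tuning_burn_in: int | None = None

    def __post_init__(self) -> None:
        if any(p <= 0 for p in self.phi_grid):
            raise ValueError("phi values must be positive")
        if any(v < 1 for v in self.v_grid):
            raise ValueError("v must be >= 1")
        if self.b1 <= 0 or self.b2 <= 0:
            raise ValueError("Gamma shapes b1, b2 must be positive")
        if self.iterations <= self.burn_in:
            raise ValueError("iterations must exceed burn_in")


@dataclass
class PosteriorState:
    """Current Gibbs state for one block (SNP-major layout)."""

    b: np.ndarray          # (2m,)
    sigma2: float
    psi: np.ndarray
    xi: np.ndarray
    rho: np.ndarray
    delta: np.ndarray
    lam: np.ndarray
    phi: float
    v: float

    @property
    def m(self) -> int:
        return self.psi.size

    def shrinkage_factors(self, f: float = 0.0) -> tuple[np.ndarray, np.ndarray, float]:
        """Diagnostic (t_j, s_j, c): t_j = 1 + 1/(phi psi_j),
        s_j = 1 - f + 1/(phi xi_j), c = sqrt((1 - f)/2)."""
        t = 1.0 + 1.0 / (self.phi * self.psi)
        s = 1.0 - f + 1.0 / (self.phi * self.xi)
        return t, s, float(np.sqrt((1.0 - f) / 2.0))


def build_omega(psi: np.ndarray, xi: np.ndarray, rho: np.ndarray, phi: float
                ) -> np.ndarray:
    """Dense 2m x 2m prior scale Omega = [[Psi, P], [P, Xi]] (diagonal blocks)."""
    m = psi.size
    omega = np.zeros((2 * m, 2 * m))
    idx = np.arange(m)
    omega[idx, idx] = phi * psi
    omega[m + idx, m + idx] = phi * xi
    omega[idx, m + idx] = omega[m + idx, idx] = phi * rho * np.sqrt(psi * xi)
    return omega


def _omega_inverse_entries(psi, xi, rho, phi):
    """Per-SNP entries of Omega^-1: (a_j, d_j, o_j) for positions
    (j,j), (m+j,m+j), (j,m+j)."""
    one_minus = 1.0 - rho**2
    a = 1.0 / (phi * psi * one_minus)
    d = 1.0 / (phi * xi * one_minus)
    o = -rho / (phi * np.sqrt(psi * xi) * one_minus)
    return a, d, o


def conditional_mean_b(b_hat: np.ndarray, D: np.ndarray, omega: np.ndarray,
                       sigma2: float = 1.0, n: int = 1
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean (D + Omega^-1)^-1 b_hat and covariance
    (sigma^2/n)(D + Omega^-1)^-1 of the effect sizes given marginal estimates."""
    omega_inv = np.linalg.inv(omega)
    A = D + omega_inv
    try:
        cf = sla.cho_factor(A)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded upstream
        raise np.linalg.LinAlgError("D + Omega^-1 is singular") from exc
    mean = sla.cho_solve(cf, np.asarray(b_hat, dtype=float))
    cov = (sigma2 / n) * sla.cho_solve(cf, np.eye(A.shape[0]))
    return mean, cov


def _sample_invwishart_2x2(s11, s22, s12, df, rng):
    """Vectorized IW draws for arrays of 2x2 scale matrices.

    Draws W ~ Wishart(df, S^-1) by Bartlett decomposition and returns
    M = W^-1 as (m11, m22, m12) arrays.
    """
    det_s = s11 * s22 - s12**2
    det_s = np.maximum(det_s, np.finfo(float).tiny)
    # analytic Cholesky of S^-1 (lower triangular A with A A' = S^-1)
    a11 = np.sqrt(s22 / det_s)
    a21 = -s12 / np.sqrt(s22 * det_s)
    a22 = 1.0 / np.sqrt(s22)
    m = s11.size
    c1 = rng.chisquare(df, size=m)
    c2 = rng.chisquare(df - 1.0, size=m)
    z = rng.standard_normal(m)
    f11 = a11 * np.sqrt(c1)
    f21 = a21 * np.sqrt(c1) + a22 * z
    f22 = a22 * np.sqrt(c2)
    w11 = f11**2
    w12 = f11 * f21
    w22 = f21**2 + f22**2
    det_w = np.maximum(w11 * w22 - w12**2, np.finfo(float).tiny)
    return w22 / det_w, w11 / det_w, -w12 / det_w


def sample_prior_M(v: float, delta: np.ndarray, lam: np.ndarray,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Prior draws M_j ~ IW(4v diag(delta_j, lambda_j), 2v + 1);
    returns (psi, xi, rho)."""
    m11, m22, m12 = _sample_invwishart_2x2(
        4.0 * v * delta, 4.0 * v * lam, np.zeros_like(delta), 2.0 * v + 1.0, rng)
    rho = m12 / np.sqrt(m11 * m22)
    return m11, m22, rho


@dataclass
class BlockDiagnostics:
    sigma2_mean: float = np.nan
    sigma2_last: float = np.nan
    cap_events: int = 0
    sweeps: int = 0
    failed: bool = False
    final_state: "PosteriorState | None" = None


def gibbs_block(b_hat: np.ndarray, D: np.ndarray, n: int, phi: float, v: float,
                hyper: BayesHyper, rng: np.random.Generator,
                iterations: int | None = None, burn_in: int | None = None,
                keep_draws: bool = False
                ) -> tuple[np.ndarray, BlockDiagnostics] | tuple[np.ndarray, BlockDiagnostics, np.ndarray]:
    """Run the Gibbs cycle for one LD block; returns posterior-mean b.

    ``b_hat`` is the stacked (beta_hat, alpha_hat) vector in SNP-major
    order matching ``D``. All randomness flows through ``rng``.
    """
    b_hat = np.asarray(b_hat, dtype=float).ravel()
    two_m = b_hat.size
    m = two_m // 2
    iterations = iterations if iterations is not None else hyper.iterations
    burn_in = burn_in if burn_in is not None else hyper.burn_in

    # initial state: unit local scales, uncorrelated, prior-mean hypers
    state = PosteriorState(
        b=np.zeros(two_m), sigma2=1.0,
        psi=np.minimum(np.ones(m), hyper.rho_cap / phi),
        xi=np.minimum(np.ones(m), hyper.rho_cap / phi),
        rho=np.zeros(m), delta=np.full(m, hyper.b1), lam=np.full(m, hyper.b2),
        phi=phi, v=v,
    )
    idx = np.arange(m)
    b_sum = np.zeros(two_m)
    kept = 0
    diag = BlockDiagnostics()
    sigma2_acc = 0.0
    draws = [] if keep_draws else None
    for sweep in range(iterations):
        # (1) b | .
        a, d, o = _omega_inverse_entries(state.psi, state.xi, state.rho, phi)
        A = D.copy()
        A[idx, idx] += a
        A[m + idx, m + idx] += d
        A[idx, m + idx] += o
        A[m + idx, idx] += o
        cf, lower = sla.cho_factor(A, lower=True)
        mean = sla.cho_solve((cf, lower), b_hat)
        z = rng.standard_normal(two_m)
        half = sla.solve_triangular(cf, z, lower=lower, trans="T")
        state.b = mean + np.sqrt(state.sigma2 / n) * half

        # (2) sigma^2 | .
        quad_data = 1.0 - 2.0 * state.b @ b_hat + state.b @ (D @ state.b)
        bq = state.b[:m]
        aq = state.b[m:]
        quad_prior = np.sum(a * bq**2 + 2.0 * o * bq * aq + d * aq**2)
        rate = 0.5 * n * max(quad_data, 0.0) + 0.5 * n * quad_prior
        shape = 0.5 * (n + two_m)
        state.sigma2 = rate / rng.gamma(shape)
        if not np.isfinite(state.sigma2) or state.sigma2 > 1e10:
            diag.failed = True
            diag.sweeps = sweep
            raise GibbsDivergenceError(
                f"sigma^2 chain diverged at sweep {sweep} (sigma2={state.sigma2:.3g})")

        # (3) M_j | . with scale B_j + (n / (sigma^2 phi)) b_j b_j'
        kappa = n / (state.sigma2 * phi)
        s11 = 4.0 * v * state.delta + kappa * bq**2
        s22 = 4.0 * v * state.lam + kappa * aq**2
        s12 = kappa * bq * aq
        psi, xi, m12 = _sample_invwishart_2x2(s11, s22, s12, 2.0 * v + 2.0, rng)
        rho = np.clip(m12 / np.sqrt(psi * xi), -1 + 1e-12, 1 - 1e-12)
        cap = hyper.rho_cap / phi
        n_capped = int(np.sum(psi > cap) + np.sum(xi > cap))
        diag.cap_events += n_capped
        # lower floor is a numerical guard only: null SNPs drive psi/xi
        # toward zero and the Omega^-1 entries would overflow
        state.psi = np.clip(psi, 1e-12, cap)
        state.xi = np.clip(xi, 1e-12, cap)
        state.rho = rho

        # (4) delta_j, lambda_j | .
        inv11 = 1.0 / (state.psi * (1.0 - state.rho**2))
        inv22 = 1.0 / (state.xi * (1.0 - state.rho**2))
        gshape = 0.5 * (2.0 * v + 1.0)
        state.delta = rng.gamma(hyper.b1 + gshape, 1.0 / (1.0 + 2.0 * v * inv11))
        state.lam = rng.gamma(hyper.b2 + gshape, 1.0 / (1.0 + 2.0 * v * inv22))

        if sweep >= burn_in and (sweep - burn_in) % hyper.thinning == 0:
            b_sum += state.b
            kept += 1
            sigma2_acc += state.sigma2
            if keep_draws:
                draws.append(state.b.copy())
    diag.sweeps = iterations
    diag.sigma2_mean = sigma2_acc / max(kept, 1)
    diag.sigma2_last = state.sigma2
    diag.final_state = state
    post_mean = b_sum / max(kept, 1)
    if keep_draws:
        return post_mean, diag, np.asarray(draws)
    return post_mean, diag


def _stack_block(ss: SummaryStats, rows: np.ndarray) -> np.ndarray:
    return np.concatenate([ss.beta_hat[rows], ss.alpha_hat[rows]])


def _run_all_blocks(ss: SummaryStats, D_blocks: list[np.ndarray],
                    block_idx: np.ndarray, phi: float, v: float,
                    hyper: BayesHyper, iterations: int, burn_in: int,
                    n_jobs: int = 1) -> tuple[np.ndarray, np.ndarray, list[BlockDiagnostics]]:
    m = ss.m
    beta = np.zeros(m)
    alpha = np.zeros(m)

    def one(bi: int):
        rows = np.flatnonzero(block_idx == bi)
        if rows.size == 0:
            return bi, rows, None, BlockDiagnostics()
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=hyper.seed, spawn_key=(bi,)))
        try:
            post, dg = gibbs_block(_stack_block(ss, rows), D_blocks[bi], ss.n,
                                   phi, v, hyper, rng,
                                   iterations=iterations, burn_in=burn_in)
        except (GibbsDivergenceError, np.linalg.LinAlgError) as exc:
            logger.warning("block %d failed (%s); zero estimates used", bi, exc)
            dg = BlockDiagnostics(failed=True)
            post = np.zeros(2 * rows.size)
        return bi, rows, post, dg

    n_blocks = len(D_blocks)
    if n_jobs != 1:
        from joblib import Parallel, delayed
        results = Parallel(n_jobs=n_jobs)(delayed(one)(bi) for bi in range(n_blocks))
    else:
        results = [one(bi) for bi in range(n_blocks)]
    diags = [BlockDiagnostics()] * n_blocks
    for bi, rows, post, dg in results:
        diags[bi] = dg
        if post is not None and rows.size:
            mb = rows.size
            beta[rows] = post[:mb]
            alpha[rows] = post[mb:]
    return beta, alpha, diags


def run_bayes(ss: SummaryStats, D_blocks: list[np.ndarray], block_idx: np.ndarray,
              hyper: BayesHyper, valid_cohort=None, n_jobs: int = 1,
              final_ss: SummaryStats | None = None) -> EffectEstimates:
    """Genome-wide posterior-mean effects with (v, phi) tuned on validation R^2.

    ``D_blocks[k]`` is the 2m_k x 2m_k joint-design correlation for the SNPs
    with ``block_idx == k`` (in summary-stat order). When a validation cohort
    is supplied, every (v, phi) grid point is evaluated by two-arm R^2 of the
    resulting score and the winner is refit at the full chain length;
    otherwise the grids must be singletons. ``final_ss`` lets the winner be
    refit on different (e.g. full-training) summary statistics while tuning
    runs on a subset disjoint from the validation cohort.
    """
    from .evaluate import two_arm_r2

    grid = [(v, phi) for v in hyper.v_grid for phi in hyper.phi_grid]
    if valid_cohort is None:
        if len(grid) != 1:
            raise ValueError("a validation cohort is required to tune (v, phi)")
        best_v, best_phi = grid[0]
    else:
        t_iters = hyper.tuning_iterations or hyper.iterations
        t_burn = hyper.tuning_burn_in if hyper.tuning_burn_in is not None else \
            min(hyper.burn_in, t_iters // 2)
        best = None
        for v, phi in grid:
            beta, alpha, _ = _run_all_blocks(ss, D_blocks, block_idx, phi, v,
                                             hyper, t_iters, t_burn, n_jobs)
            est = EffectEstimates(ss.table, beta, alpha, "PRS-PGx-Bayes",
                                  mu_t=ss.mu_t, params={"v": v, "phi": phi})
            r2 = two_arm_r2(valid_cohort, est)
            if best is None or r2 > best[0]:
                best = (r2, v, phi)
        _, best_v, best_phi = best
    ss = final_ss if final_ss is not None else ss
    beta, alpha, diags = _run_all_blocks(ss, D_blocks, block_idx, best_phi, best_v,
                                         hyper, hyper.iterations, hyper.burn_in, n_jobs)
    n_failed = sum(d.failed for d in diags)
    if n_failed:
        logger.warning("run_bayes: %d block(s) failed and contribute zero weights",
                       n_failed)
    return EffectEstimates(
        ss.table, beta, alpha, "PRS-PGx-Bayes", mu_t=ss.mu_t,
        params={"v": best_v, "phi": best_phi,
                "diagnostics": [{k: val for k, val in vars(d).items()
                                 if k != "final_state"} for d in diags]},
    )
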