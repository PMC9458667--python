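"""Score construction, prediction metrics, stratification, and the
disease-PRS attainability theory.

Scores follow the two-arm decomposition: with estimated per-SNP weights
(beta_est, alpha_est),

    S_prog = sum_j beta_est_j G_j,   S_pred = sum_j alpha_est_j G_j,
    S_PGx  = S_prog + S_pred  for treated subjects, S_prog otherwise.

Prediction accuracy is the squared Pearson correlation between the
covariate/treatment-adjusted phenotype and the score, within two arms or
a single arm. The predictive component is tested by a 1-df likelihood
ratio test of the S_pred x T interaction.

``attainable_fraction`` evaluates the closed-form ceiling on
cor^2(S_Dis, Y)/h^2: the share of drug-response heritability a
main-effects-only (disease) PRS can attain given the variance components
(psi, xi) and correlations rho of the prognostic/predictive effect-size
distribution. It equals 1 exactly when every variant has perfectly
proportional effects (rho = 1, psi proportional to xi), i.e. the
constant-ratio condition beta_i = c * alpha_i.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import EffectEstimates, PGxCohort


@dataclass
class PGxScores:
    """Per-subject prognostic, predictive and combined scores."""

    s_prog: np.ndarray
    s_pred: np.ndarray
    s_pgx: np.ndarray
    T: np.ndarray


@dataclass
class EvalReport:
    r2_two_arm: float
    r2_treatment: float
    r2_control: float
    p_interaction: float
    p_score_treatment: float
    p_score_control: float
    stratification: pd.DataFrame | None = None
    method: str = ""


def compute_scores(G: np.ndarray, T: np.ndarray, est: EffectEstimates) -> PGxScores:
    """Weighted genotype sums with the two-arm combination rule.

    ``G`` must be on the scale the weights were estimated for (standardized
    dosages throughout this package). The interaction weights are rescaled
    from the standardized-interaction-column scale via ``est.mu_t``.
    """
    G = np.asarray(G, dtype=float)
    if G.shape[1] != est.m:
        raise ValueError(f"genotype matrix has {G.shape[1]} SNPs but weights have {est.m}")
    T = np.asarray(T, dtype=float).ravel()
    s_prog = G @ est.beta_est
    s_pred = G @ est.genotype_scale_alpha()
    s_pgx = s_prog + T * s_pred
    return PGxScores(s_prog=s_prog, s_pred=s_pred, s_pgx=s_pgx, T=T)


def adjust_phenotype(Y: np.ndarray, X: np.ndarray, T: np.ndarray) -> np.ndarray:
    """Residual of Y on [1, X, T] by least squares."""
    Y = np.asarray(Y, dtype=float).ravel()
    design = np.column_stack([np.ones(Y.shape[0]), np.atleast_2d(X), np.asarray(T).ravel()])
    coef, *_ = np.linalg.lstsq(design, Y, rcond=None)
    return Y - design @ coef


def r2_by_arm(y_adj: np.ndarray, scores: PGxScores, arm: str = "both") -> float:
    """Squared Pearson correlation between y_adj and S_PGx within an arm.

    ``arm`` is 'both', 'T' (treatment) or 'C' (control). A constant score
    yields R^2 = 0 with a warning rather than NaN.
    """
    y_adj = np.asarray(y_adj, dtype=float).ravel()
    if arm == "both":
        mask = np.ones_like(y_adj, dtype=bool)
    elif arm == "T":
        mask = scores.T == 1
    elif arm == "C":
        mask = scores.T == 0
    else:
        raise ValueError(f"unknown arm {arm!r}")
    s = scores.s_pgx[mask]
    y = y_adj[mask]
    if np.std(s) == 0 or np.std(y) == 0:
        warnings.warn("degenerate (constant) score or response; R^2 set to 0")
        return 0.0
    r = np.corrcoef(s, y)[0, 1]
    return float(r * r)


def two_arm_r2(cohort: PGxCohort, est: EffectEstimates) -> float:
    """Convenience: adjust the cohort phenotype, score it, return two-arm R^2."""
    from .io import standardize

    c = cohort if cohort.standardized else standardize(cohort)
    scores = compute_scores(c.G, c.T, est)
    return r2_by_arm(c.Y, scores, arm="both")


def _ols_loglike(y: np.ndarray, design: np.ndarray) -> float:
    n = y.shape[0]
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    rss = float(np.sum((y - design @ coef) ** 2))
    return -0.5 * n * (np.log(2 * np.pi * rss / n) + 1)


def lrt_interaction(y_adj: np.ndarray, s_prog: np.ndarray, s_pred: np.ndarray,
                    T: np.ndarray) -> float:
    """LRT p-value for the S_pred x T term in y_adj ~ S_prog + S_pred * T.

    The comparison is a 1-df chi-square between the full model
    [1, S_prog, S_pred, T, S_pred*T] and the same model without the
    interaction. A constant predictive score makes the test undefined and
    returns p = 1 with a warning.
    """
    y_adj = np.asarray(y_adj, dtype=float).ravel()
    s_pred = np.asarray(s_pred, dtype=float).ravel()
    T = np.asarray(T, dtype=float).ravel()
    if np.std(s_pred) == 0 or np.std(s_pred * T) == 0:
        warnings.warn("constant predictive score: interaction test undefined, p = 1")
        return 1.0
    ones = np.ones_like(y_adj)
    reduced = np.column_stack([ones, s_prog, s_pred, T])
    full = np.column_stack([reduced, s_pred * T])
    lr = 2.0 * (_ols_loglike(y_adj, full) - _ols_loglike(y_adj, reduced))
    return float(np.clip(stats.chi2.sf(max(lr, 0.0), df=1), np.finfo(float).tiny, 1.0))


def lrt_score(y: np.ndarray, score: np.ndarray) -> float:
    """1-df LRT p-value for a single score term in y ~ score."""
    y = np.asarray(y, dtype=float).ravel()
    score = np.asarray(score, dtype=float).ravel()
    if np.std(score) == 0:
        warnings.warn("constant score: test undefined, p = 1")
        return 1.0
    ones = np.ones_like(y)
    lr = 2.0 * (_ols_loglike(y, np.column_stack([ones, score])) - _ols_loglike(y, ones[:, None]))
    return float(np.clip(stats.chi2.sf(max(lr, 0.0), df=1), np.finfo(float).tiny, 1.0))


# ---------------------------------------------------------------------------
# patient stratification
# ---------------------------------------------------------------------------

def _arm_diff(y: np.ndarray, t: np.ndarray) -> tuple[float, float, float, float, float]:
    """Treatment effect (difference of arm means) with a normal-approx 95% CI."""
    y1, y0 = y[t == 1], y[t == 0]
    if y1.size == 0 or y0.size == 0:
        return np.nan, np.nan, np.nan, np.nan, np.nan
    te = float(y1.mean() - y0.mean())
    se = float(np.sqrt(y1.var(ddof=1) / y1.size + y0.var(ddof=1) / y0.size)) \
        if min(y1.size, y0.size) > 1 else np.nan
    lo, hi = te - 1.96 * se, te + 1.96 * se
    return float(y1.mean()), float(y0.mean()), te, lo, hi


def stratify(Y: np.ndarray, T: np.ndarray, s_pred: np.ndarray,
             quantiles: int | None = 4, top_fraction: float | None = None
             ) -> pd.DataFrame:
    """Subgroup treatment effects along the predictive score.

    Quantile mode splits subjects into ``quantiles`` equal-count bins of
    S_pred. Top-fraction mode compares the top ``top_fraction`` of S_pred
    against the rest, adding a differential treatment effect row
    (TE(top) - TE(rest)).
    """
    Y = np.asarray(Y, dtype=float).ravel()
    T = np.asarray(T, dtype=float).ravel()
    s = np.asarray(s_pred, dtype=float).ravel()
    rows = []
    if top_fraction is not None:
        cut = np.quantile(s, 1.0 - top_fraction)
        groups = [("rest", s < cut), (f"top{top_fraction:.0%}", s >= cut)]
        for label, mask in groups:
            m1, m0, te, lo, hi = _arm_diff(Y[mask], T[mask])
            rows.append({"subgroup": label, "n": int(mask.sum()),
                         "mean_T": m1, "mean_C": m0, "te": te,
                         "ci_lo": lo, "ci_hi": hi})
        tab = pd.DataFrame(rows)
        tab["differential_te"] = tab["te"].iloc[1] - tab["te"].iloc[0]
        return tab
    if quantiles is None or quantiles < 2:
        raise ValueError("need quantiles >= 2 or a top_fraction")
    edges = np.quantile(s, np.linspace(0, 1, quantiles + 1))
    bins = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, quantiles - 1)
    for q in range(quantiles):
        mask = bins == q
        m1, m0, te, lo, hi = _arm_diff(Y[mask], T[mask])
        rows.append({"subgroup": f"q{q + 1}", "lo": edges[q], "hi": edges[q + 1],
                     "n": int(mask.sum()), "mean_T": m1, "mean_C": m0,
                     "te": te, "ci_lo": lo, "ci_hi": hi})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# attainability theory
# ---------------------------------------------------------------------------

def attainable_fraction(psi: np.ndarray, xi: np.ndarray, rho: np.ndarray) -> float:
    """Fraction of drug-response heritability a disease PRS can attain.

    Evaluates, for per-variant prognostic variances psi_i, predictive
    variances xi_i and effect correlations rho_i,

        1 - (S_psi S_xi - (sum_i rho_i sqrt(psi_i xi_i))^2)
            / (S_psi^2 + 2 S_psi sum_i rho_i sqrt(psi_i xi_i) + S_psi S_xi)

    with S_psi = sum_i psi_i, S_xi = sum_i xi_i. Multiplying by h^2 gives
    cor^2(S_Dis, Y) for treated subjects.
    """
    psi = np.asarray(psi, dtype=float).ravel()
    xi = np.asarray(xi, dtype=float).ravel()
    rho = np.asarray(rho, dtype=float).ravel()
    if psi.size == 0 or (np.all(psi == 0) and np.all(xi == 0)):
        raise ValueError("attainable fraction undefined for all-zero variance components")
    if np.any(psi < 0) or np.any(xi < 0):
        raise ValueError("variance components must be non-negative")
    s_psi = psi.sum()
    s_xi = xi.sum()
    s_cross = float(np.sum(rho * np.sqrt(psi * xi)))
    num = s_psi * s_xi - s_cross**2
    den = s_psi**2 + 2 * s_psi * s_cross + s_psi * s_xi
    return float(1.0 - num / den)


def ratio_distribution(est: EffectEstimates, p2df: np.ndarray,
                       p_thresholds: tuple[float, ...] = (1e-06, 1e-05, 1e-04),
                       kept_idx: np.ndarray | None = None) -> pd.DataFrame:
    """Five-number summaries of prognostic/predictive ratios beta/alpha.

    Computed over all (optionally clumped) SNPs and within each p-value
    threshold subset. SNPs with alpha exactly zero are excluded and counted.
    """
    idx = np.arange(est.m) if kept_idx is None else np.asarray(kept_idx)
    beta = est.beta_est[idx]
    alpha = est.alpha_est[idx]
    p = np.asarray(p2df, dtype=float)[idx]
    rows = []
    for label, mask in [("all", np.ones(idx.size, dtype=bool))] + \
            [(f"p<{t:g}", p < t) for t in p_thresholds]:
        a, b = alpha[mask], beta[mask]
        nz = a != 0
        ratios = b[nz] / a[nz]
        if ratios.size:
            q = np.percentile(ratios, [0, 25, 50, 75, 100])
        else:
            q = [np.nan] * 5
        rows.append({"subset": label, "n": int(mask.sum()),
                     "n_excluded_zero_alpha": int(mask.sum() - nz.sum()),
                     "min": q[0], "q1": q[1], "median": q[2], "q3": q[3], "max": q[4]})
    return pd.DataFrame(rows)


def evaluate_method(test_cohort: PGxCohort, est: EffectEstimates,
                    stratify_quantiles: int | None = 4) -> EvalReport:
    """Full evaluation of one method's weights on a held-out test cohort."""
    from .io import standardize

    c = test_cohort if test_cohort.standardized else standardize(test_cohort)
    scores = compute_scores(c.G, c.T, est)
    y_adj = c.Y  # standardization already residualizes on [1, X, T]
    strat = None
    if stratify_quantiles and np.std(scores.s_pred) > 0:
        strat = stratify(y_adj, c.T, scores.s_pred, quantiles=stratify_quantiles)
    t_mask, c_mask = c.T == 1, c.T == 0
    return EvalReport(
        r2_two_arm=r2_by_arm(y_adj, scores, "both"),
        r2_treatment=r2_by_arm(y_adj, scores, "T"),
        r2_control=r2_by_arm(y_adj, scores, "C"),
        p_interaction=lrt_interaction(y_adj, scores.s_prog, scores.s_pred, c.T),
        p_score_treatment=lrt_score(y_adj[t_mask], scores.s_pgx[t_mask]),
        p_score_control=lrt_score(y_adj[c_mask], scores.s_pgx[c_mask]),
        stratification=strat,
        method=est.method,
    )
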