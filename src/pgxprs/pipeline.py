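"""Orchestration: LD preparation, method fitting, nested cross-validation
and the desk-scale simulation benchmark.

`run_benchmark` loops replicates of the synthetic study design
(:func:`pgxprs.simulate.make_benchmark_scenario`), fits the requested
methods on the training cohort (tuning on a stratified 80/20 validation
split of it), evaluates on the held-out test cohort, and returns a tidy
long-format table of prediction metrics.

`run_nested_cv` reproduces the trial-analysis workflow: outer folds for
unbiased evaluation, inner validation for tuning, with out-of-fold scores
concatenated before a single final evaluation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import basic, evaluate as ev
from .bayes import BayesHyper, run_bayes
from .io import (EffectEstimates, PGxCohort, SummaryStats,
                 compute_disease_summary_stats, compute_summary_stats, standardize)
from .ld import build_D, ld_matrix
from .simulate import SimConfig, SimScenario, make_benchmark_scenario

logger = logging.getLogger(__name__)

#: desk-scale tuning grid for the Bayes sampler used by the benchmark
BENCHMARK_BAYES_HYPER = dict(
    phi_grid=(1e-2, 1e-1, 1.0), v_grid=(2.0, 5.0),
    iterations=1000, burn_in=500, tuning_iterations=400, tuning_burn_in=200,
)


@dataclass
class LDContext:
    """Reference-panel LD prepared for one SNP set."""

    sigma_blocks: list[np.ndarray]
    D_blocks: list[np.ndarray]
    block_idx: np.ndarray


def prepare_ld(ref_G: np.ndarray, block_idx: np.ndarray, mu_t: float) -> LDContext:
    """Block Sigma and joint D matrices from reference genotypes."""
    n_blocks = int(block_idx.max()) + 1 if block_idx.size else 0
    sigma_blocks, d_blocks = [], []
    for bi in range(n_blocks):
        cols = np.flatnonzero(block_idx == bi)
        if cols.size == 0:
            sigma_blocks.append(np.empty((0, 0)))
            d_blocks.append(np.empty((0, 0)))
            continue
        sigma, kept = ld_matrix(ref_G[:, cols])
        if kept.size < cols.size:
            # monomorphic panel SNPs: fall back to identity rows (no LD info)
            full = np.eye(cols.size)
            full[np.ix_(kept, kept)] = sigma
            sigma = full
        sigma_blocks.append(sigma)
        d_blocks.append(build_D(sigma, mu_t).D)
    return LDContext(sigma_blocks=sigma_blocks, D_blocks=d_blocks, block_idx=block_idx)


def split_validation(cohort: PGxCohort, frac: float = 0.2,
                     rng: np.random.Generator | int = 0
                     ) -> tuple[PGxCohort, PGxCohort]:
    """Stratified-by-arm split into (subtrain, validation)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    val_idx = []
    for arm in (0, 1):
        rows = np.flatnonzero(cohort.T == arm)
        rows = rng.permutation(rows)
        val_idx.append(rows[:max(1, int(round(frac * rows.size)))])
    val = np.sort(np.concatenate(val_idx))
    sub = np.setdiff1d(np.arange(cohort.n), val)
    return cohort.subset(sub), cohort.subset(val)


def _block_idx_from_bounds(bounds: list[tuple[int, int]], m: int) -> np.ndarray:
    out = np.empty(m, dtype=int)
    for bi, (s, e) in enumerate(bounds):
        out[s:e] = bi
    return out


def fit_bayes(train: PGxCohort, bounds: list[tuple[int, int]], ref_G: np.ndarray,
              hyper: BayesHyper, rng: np.random.Generator) -> EffectEstimates:
    """Tune (v, phi) on a stratified validation split, refit on the full
    training summary statistics."""
    sub, val = split_validation(train, rng=rng)
    ss_sub = compute_summary_stats(sub)
    ss_full = compute_summary_stats(train)
    block_idx = _block_idx_from_bounds(bounds, ss_full.m)
    ld = prepare_ld(ref_G, block_idx, ss_full.mu_t)
    return run_bayes(ss_sub, ld.D_blocks, block_idx, hyper,
                     valid_cohort=val, final_ss=ss_full)


def fit_ct(train: PGxCohort, bounds: list[tuple[int, int]], ref_G: np.ndarray,
           config: basic.CTConfig, rng: np.random.Generator) -> EffectEstimates:
    sub, val = split_validation(train, rng=rng)
    ss_sub = compute_summary_stats(sub)
    ss_full = compute_summary_stats(train)
    block_idx = _block_idx_from_bounds(bounds, ss_full.m)
    ld = prepare_ld(ref_G, block_idx, ss_full.mu_t)
    p_t, _ = basic.select_threshold(ss_sub, val, ld.sigma_blocks, block_idx, config)
    return basic.prs_pgx_ct(ss_full, ld.sigma_blocks, block_idx, config, p_t)


def fit_disease_ct(disease: PGxCohort, valid: PGxCohort,
                   bounds: list[tuple[int, int]], ref_G: np.ndarray,
                   config: basic.CTConfig) -> EffectEstimates:
    """Disease C+T baseline: weights from the large main-effects cohort,
    threshold tuned on a PGx validation cohort."""
    dis_ss = compute_disease_summary_stats(disease)
    block_idx = _block_idx_from_bounds(bounds, len(dis_ss))
    ld = prepare_ld(ref_G, block_idx, 0.5)  # mu_t unused by main-effect clumping
    best = None
    for p_t in sorted(config.pt_grid):
        est = basic.prs_dis_ct(dis_ss, ld.sigma_blocks, block_idx, config, p_t)
        r2 = ev.two_arm_r2(valid, est)
        if best is None or r2 > best[0] + 1e-12:
            best = (r2, est)
    return best[1]


def run_benchmark(config: SimConfig, methods: tuple[str, ...] = ("bayes", "dis_ct"),
                  replicates: int = 20, seed: int = 0,
                  bayes_hyper: dict | None = None) -> pd.DataFrame:
    """Replicated method comparison on the synthetic study design.

    Returns one row per (replicate, method) with test-set metrics; method
    failures are recorded as NaN rows, not raised.
    """
    rows = []
    hyper_kw = dict(BENCHMARK_BAYES_HYPER)
    if bayes_hyper:
        hyper_kw.update(bayes_hyper)
    for rep in range(replicates):
        ss_rng = np.random.SeedSequence(entropy=seed, spawn_key=(rep,))
        rng = np.random.default_rng(ss_rng)
        scen = make_benchmark_scenario(config, rng)
        sub, val = None, None
        for method in methods:
            try:
                est = _fit_method(method, scen, hyper_kw, seed, rep)
                report = ev.evaluate_method(scen.test, est, stratify_quantiles=None)
                rows.append({
                    "replicate": rep, "method": est.method,
                    "r2_two_arm": report.r2_two_arm,
                    "r2_treatment": report.r2_treatment,
                    "r2_control": report.r2_control,
                    "neglog10_p_interaction": -np.log10(report.p_interaction),
                    "n_causal": int(scen.effects.causal.sum()),
                })
            except Exception as exc:  # noqa: BLE001 - benchmark must not abort
                logger.warning("replicate %d method %s failed: %s", rep, method, exc)
                rows.append({"replicate": rep, "method": method,
                             "r2_two_arm": np.nan, "r2_treatment": np.nan,
                             "r2_control": np.nan,
                             "neglog10_p_interaction": np.nan,
                             "n_causal": int(scen.effects.causal.sum())})
    return pd.DataFrame(rows)


def _fit_method(method: str, scen: SimScenario, hyper_kw: dict,
                seed: int, rep: int) -> EffectEstimates:
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(rep, hash(method) % (2**31))))
    ct_cfg = basic.CTConfig()
    if method == "bayes":
        hyper = BayesHyper(seed=int(rng.integers(2**31)), **hyper_kw)
        return fit_bayes(scen.train, scen.block_bounds, scen.ref_G, hyper, rng)
    if method == "ct":
        return fit_ct(scen.train, scen.block_bounds, scen.ref_G, ct_cfg, rng)
    if method == "unadj":
        return basic.prs_pgx_unadj(compute_summary_stats(scen.train))
    if method == "dis_ct":
        _, val = split_validation(scen.train, rng=rng)
        return fit_disease_ct(scen.disease, val, scen.block_bounds, scen.ref_G, ct_cfg)
    if method in ("lasso", "gl", "sgl"):
        from .penalized import select_lambda
        sub, val = split_validation(scen.train, rng=rng)
        _, est = select_lambda(sub, val, method=method)
        return est
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# nested cross-validation
# ---------------------------------------------------------------------------

@dataclass
class NestedCVPlan:
    outer_folds: int = 5
    inner_folds: int = 4
    seed: int = 0
    fold_of: np.ndarray | None = None


def _stratified_folds(T: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    fold = np.empty(T.size, dtype=int)
    for arm in (0, 1):
        rows = rng.permutation(np.flatnonzero(T == arm))
        fold[rows] = np.arange(rows.size) % k
    return fold


def run_nested_cv(cohort: PGxCohort, bounds: list[tuple[int, int]],
                  methods: tuple[str, ...] = ("unadj", "ct"),
                  plan: NestedCVPlan | None = None,
                  bayes_hyper: dict | None = None) -> dict:
    """Outer-fold evaluation with inner-validation tuning.

    Training folds produce summary statistics and tuned weights; only the
    held-out fold's prognostic/predictive scores are recorded. Returns
    per-method reports over the concatenated out-of-fold scores, plus the
    per-fold weights (for leakage auditing).
    """
    plan = plan or NestedCVPlan()
    rng = np.random.default_rng(plan.seed)
    fold = plan.fold_of if plan.fold_of is not None else \
        _stratified_folds(cohort.T, plan.outer_folds, rng)
    for f in range(plan.outer_folds):
        t_fold = cohort.T[fold == f]
        if t_fold.size < 2 or len(np.unique(t_fold)) < 2:
            raise ValueError("a fold has a single treatment arm; use more subjects")
    reports: dict[str, ev.EvalReport] = {}
    fold_weights: dict[str, list[EffectEstimates]] = {m: [] for m in methods}
    oof = {m: {"s_prog": np.zeros(cohort.n), "s_pred": np.zeros(cohort.n)}
           for m in methods}
    ct_cfg = basic.CTConfig()
    for f in range(plan.outer_folds):
        test_idx = np.flatnonzero(fold == f)
        train_idx = np.flatnonzero(fold != f)
        train = cohort.subset(train_idx)
        test = standardize(cohort.subset(test_idx))
        ref_G = train.G  # in-sample LD reference
        for method in methods:
            frng = np.random.default_rng(
                np.random.SeedSequence(entropy=plan.seed, spawn_key=(f,)))
            if method == "bayes":
                kw = dict(BENCHMARK_BAYES_HYPER)
                if bayes_hyper:
                    kw.update(bayes_hyper)
                est = fit_bayes(train, bounds, ref_G,
                                BayesHyper(seed=int(frng.integers(2**31)), **kw), frng)
            elif method == "ct":
                est = fit_ct(train, bounds, ref_G, ct_cfg, frng)
            elif method == "unadj":
                est = basic.prs_pgx_unadj(compute_summary_stats(train))
            elif method in ("lasso", "gl", "sgl"):
                from .penalized import select_lambda
                sub, val = split_validation(train, rng=frng)
                _, est = select_lambda(sub, val, method=method)
            else:
                raise ValueError(f"unknown method {method!r}")
            fold_weights[method].append(est)
            scores = ev.compute_scores(test.G, test.T, est)
            oof[method]["s_prog"][test_idx] = scores.s_prog
            oof[method]["s_pred"][test_idx] = scores.s_pred
    y_adj = ev.adjust_phenotype(cohort.Y, cohort.X, cohort.T)
    for method in methods:
        s_prog = oof[method]["s_prog"]
        s_pred = oof[method]["s_pred"]
        scores = ev.PGxScores(s_prog=s_prog, s_pred=s_pred,
                              s_pgx=s_prog + cohort.T * s_pred, T=cohort.T)
        t_mask, c_mask = cohort.T == 1, cohort.T == 0
        reports[method] = ev.EvalReport(
            r2_two_arm=ev.r2_by_arm(y_adj, scores, "both"),
            r2_treatment=ev.r2_by_arm(y_adj, scores, "T"),
            r2_control=ev.r2_by_arm(y_adj, scores, "C"),
            p_interaction=ev.lrt_interaction(y_adj, s_prog, s_pred, cohort.T),
            p_score_treatment=ev.lrt_score(y_adj[t_mask], scores.s_pgx[t_mask]),
            p_score_control=ev.lrt_score(y_adj[c_mask], scores.s_pgx[c_mask]),
            method=method,
        )
    return {"reports": reports, "fold_of": fold, "fold_weights": fold_weights,
            "oof_scores": oof}
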