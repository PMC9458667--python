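"""Domain containers and I/O for two-arm pharmacogenomics (PGx) cohorts.

The central objects are

``PGxCohort``
    individual-level data from a randomized two-arm trial: quantitative
    response ``Y``, treatment indicator ``T``, covariates ``X`` and genotype
    dosages ``G`` (n subjects x m SNPs), plus per-SNP metadata.

``SummaryStats``
    per-SNP marginal prognostic (G) and predictive (G x T) effect estimates
    on the standardized scale, together with the 2-df joint-test p-value and
    the cohort scalars (n, mean of treatment, phenotype SD) needed by the
    summary-statistics methods.

``EffectEstimates``
    the universal output contract of every scoring method: per-SNP
    (beta_est, alpha_est) weights on the standardized scale.

Genotypes are read from plain/bgzipped VCF (via cyvcf2) or PLINK1
bed/bim/fam files (2-bit hard calls, decoded here directly).
"""

from __future__ import annotations

import json
import logging
import struct
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

SNP_META_COLUMNS = ["chrom", "pos", "ref", "alt", "maf"]

#: column order of the summary-statistics TSV interchange format
SUMSTAT_COLUMNS = [
    "chrom", "pos", "ref", "alt", "maf",
    "beta_hat", "alpha_hat", "se_beta", "se_alpha", "p2df",
]


class MonomorphicSNPError(ValueError):
    """Raised when a genotype column has zero variance and cannot be standardized."""

    def __init__(self, snp_ids: Sequence[str]):
        self.snp_ids = list(snp_ids)
        super().__init__(f"monomorphic SNP(s) with zero variance: {self.snp_ids}")


@dataclass
class PGxCohort:
    """Individual-level two-arm trial data.

    Attributes
    ----------
    Y : (n,) response; T : (n,) treatment indicator in {0,1};
    X : (n, p) covariates (p may be 0); G : (n, m) genotype dosages;
    snp_meta : per-SNP chrom/pos/ref/alt/maf DataFrame;
    standardized : whether `standardize` has been applied;
    g_scale, y_scale : column SDs of G and SD of Y recorded at
        standardization time, for mapping weights back to dosage scale.
    """

    Y: np.ndarray
    T: np.ndarray
    X: np.ndarray
    G: np.ndarray
    snp_meta: pd.DataFrame
    standardized: bool = False
    g_scale: np.ndarray | None = None
    y_scale: float | None = None

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float).ravel()
        self.T = np.asarray(self.T, dtype=float).ravel()
        self.G = np.asarray(self.G, dtype=float)
        if self.X is None or (hasattr(self.X, "size") and np.asarray(self.X).size == 0):
            self.X = np.empty((self.Y.shape[0], 0))
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        n = self.Y.shape[0]
        if not (self.T.shape[0] == n == self.G.shape[0] == self.X.shape[0]):
            raise ValueError(
                f"row mismatch: Y={self.Y.shape[0]}, T={self.T.shape[0]}, "
                f"G={self.G.shape[0]}, X={self.X.shape[0]}"
            )
        if len(self.snp_meta) != self.G.shape[1]:
            raise ValueError("snp_meta rows must match G columns")

    @property
    def n(self) -> int:
        return self.Y.shape[0]

    @property
    def m(self) -> int:
        return self.G.shape[1]

    def subset(self, idx: np.ndarray) -> "PGxCohort":
        """Row subset (subjects). SNP set and scaling state are preserved."""
        idx = np.asarray(idx)
        return replace(
            self, Y=self.Y[idx], T=self.T[idx], X=self.X[idx], G=self.G[idx],
            snp_meta=self.snp_meta.copy(),
        )


@dataclass
class SummaryStats:
    """Per-SNP marginal PGx GWAS estimates plus cohort scalars.

    ``beta_hat``/``alpha_hat`` are the X'Y/n inner products of the
    standardized joint design [G, GxT] with the standardized response:
    marginal estimates on the standardized scale. ``p2df`` is the per-SNP
    2-df Wald p-value of the joint hypothesis (G coefficient, GxT
    coefficient) = 0.
    """

    table: pd.DataFrame
    n: int
    mu_t: float
    sd_y: float

    def __post_init__(self) -> None:
        missing = [c for c in SUMSTAT_COLUMNS if c not in self.table.columns
                   and c not in ("se_beta", "se_alpha")]
        if missing:
            raise ValueError(f"summary stats missing columns: {missing}")
        p = np.asarray(self.table["p2df"], dtype=float)
        if np.any((p <= 0) | (p > 1)):
            raise ValueError("p2df values must lie in (0, 1]")
        if self.n <= 0:
            raise ValueError("n must be positive")
        if not 0 < self.mu_t < 1:
            raise ValueError("mu_t must lie in (0, 1)")

    @property
    def m(self) -> int:
        return len(self.table)

    @property
    def beta_hat(self) -> np.ndarray:
        return np.asarray(self.table["beta_hat"], dtype=float)

    @property
    def alpha_hat(self) -> np.ndarray:
        return np.asarray(self.table["alpha_hat"], dtype=float)

    @property
    def p2df(self) -> np.ndarray:
        return np.asarray(self.table["p2df"], dtype=float)

    def sort(self) -> "SummaryStats":
        tab = self.table.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
        pos = tab.groupby("chrom")["pos"]
        if (pos.diff().dropna() <= 0).any():
            raise ValueError("positions must be strictly increasing within chromosome")
        return SummaryStats(tab, self.n, self.mu_t, self.sd_y)


@dataclass
class EffectEstimates:
    """Per-SNP (beta_est, alpha_est) weights produced by any method.

    Weights live on the standardized scale used at fitting time. ``mu_t``
    records the interaction-column standardization: model-scale alpha weights
    (fit against the standardized GxT column) must be divided by sqrt(mu_t)
    to act on the standardized genotype directly; ``mu_t = 1`` means
    alpha_est is already on the genotype scale (e.g. simulated true effects).
    """

    snp_meta: pd.DataFrame
    beta_est: np.ndarray
    alpha_est: np.ndarray
    method: str
    mu_t: float = 1.0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.beta_est = np.asarray(self.beta_est, dtype=float).ravel()
        self.alpha_est = np.asarray(self.alpha_est, dtype=float).ravel()
        if not (len(self.snp_meta) == self.beta_est.size == self.alpha_est.size):
            raise ValueError("effect estimate length mismatch with snp_meta")
        if not (np.all(np.isfinite(self.beta_est)) and np.all(np.isfinite(self.alpha_est))):
            raise ValueError("effect estimates must be finite")

    @property
    def m(self) -> int:
        return self.beta_est.size

    def genotype_scale_alpha(self) -> np.ndarray:
        """Predictive weights rescaled to act on the standardized genotype."""
        return self.alpha_est / np.sqrt(self.mu_t)


# ---------------------------------------------------------------------------
# standardization and summary statistics
# ---------------------------------------------------------------------------

def standardize(cohort: PGxCohort) -> PGxCohort:
    """Residualize Y on [1, X, T], scale it to unit variance, and center/scale
    each genotype column.

    Idempotent within floating tolerance. Raises :class:`MonomorphicSNPError`
    when a genotype column is constant. Scaling factors are retained on the
    returned cohort for mapping weights back to dosage scale.
    """
    y = cohort.Y.astype(float)
    sd_y_orig = float(np.std(y)) if cohort.y_scale is None else cohort.y_scale
    design = np.column_stack([np.ones(cohort.n), cohort.X, cohort.T])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    sd_r = float(np.std(resid))
    if sd_r == 0:
        raise ValueError("response is fully explained by [1, X, T]; nothing to model")
    y_std = resid / sd_r

    g_sd = cohort.G.std(axis=0)
    bad = np.flatnonzero(g_sd == 0)
    if bad.size:
        ids = [f"{cohort.snp_meta['chrom'].iloc[j]}:{cohort.snp_meta['pos'].iloc[j]}" for j in bad]
        raise MonomorphicSNPError(ids)
    g_std = (cohort.G - cohort.G.mean(axis=0)) / g_sd

    prev_scale = cohort.g_scale if cohort.g_scale is not None else np.ones(cohort.m)
    return replace(
        cohort, Y=y_std, G=g_std, standardized=True,
        g_scale=prev_scale * g_sd, y_scale=sd_y_orig,
    )


def _joint_2df_wald(g: np.ndarray, w: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorized per-SNP 2-df Wald chi-square p-value for Y ~ G_j + W_j.

    ``g``/``w`` are (n, m) column-centered designs, ``y`` (n,) centered.
    The Wald statistic uses the fitted 2x2 coefficient covariance
    sigma_hat^2 (X_j'X_j)^{-1}, so the strong correlation between G_j and
    G_j x T is accounted for.
    """
    n = y.shape[0]
    sgg = np.einsum("ij,ij->j", g, g)
    sww = np.einsum("ij,ij->j", w, w)
    sgw = np.einsum("ij,ij->j", g, w)
    sgy = g.T @ y
    swy = w.T @ y
    det = sgg * sww - sgw**2
    if np.any(det <= 0):
        raise ValueError("collinear G and GxT columns in 2-df test")
    b_g = (sww * sgy - sgw * swy) / det
    b_w = (sgg * swy - sgw * sgy) / det
    yy = float(y @ y)
    rss = yy - (b_g * sgy + b_w * swy)
    dof = n - 3  # intercept absorbed by centering, 2 slopes
    sigma2 = np.maximum(rss, 0.0) / dof
    # Wald: b' (X'X) b / sigma2 with the 2x2 cross-product matrix
    quad = b_g**2 * sgg + 2 * b_g * b_w * sgw + b_w**2 * sww
    chi2 = quad / np.maximum(sigma2, np.finfo(float).tiny)
    p = stats.chi2.sf(chi2, df=2)
    return np.clip(p, np.finfo(float).tiny, 1.0)


def compute_summary_stats(cohort: PGxCohort) -> SummaryStats:
    """Marginal (beta_hat, alpha_hat) = X'Y/n on the standardized joint design,
    plus the per-SNP 2-df Wald p-value from the joint fit Y ~ G_j + G_j x T.

    The interaction columns are formed from the standardized genotypes and
    then standardized themselves, so that the joint design has a proper
    correlation matrix.
    """
    if cohort.n <= 2:
        raise ValueError("need n > 2 subjects to compute summary statistics")
    t = cohort.T
    mu_t = float(t.mean())
    if mu_t in (0.0, 1.0):
        raise ValueError("single-arm cohort: GxT interaction is not identifiable")
    c = cohort if cohort.standardized else standardize(cohort)

    g = c.G
    w_raw = g * t[:, None]
    w_centered = w_raw - w_raw.mean(axis=0)
    w_sd = w_centered.std(axis=0)
    if np.any(w_sd == 0):
        raise ValueError("constant interaction column; check treatment assignment")
    w = w_centered / w_sd

    n = c.n
    beta_hat = g.T @ c.Y / n
    alpha_hat = w.T @ c.Y / n
    p2df = _joint_2df_wald(g, w, c.Y)

    # SEs of the marginal univariate regressions on standardized columns
    resid_b = 1.0 - beta_hat**2
    resid_a = 1.0 - alpha_hat**2
    se_beta = np.sqrt(np.maximum(resid_b, 0.0) / max(n - 2, 1))
    se_alpha = np.sqrt(np.maximum(resid_a, 0.0) / max(n - 2, 1))

    table = c.snp_meta[SNP_META_COLUMNS].copy()
    table["beta_hat"] = beta_hat
    table["alpha_hat"] = alpha_hat
    table["se_beta"] = se_beta
    table["se_alpha"] = se_alpha
    table["p2df"] = p2df
    sd_y = c.y_scale if c.y_scale is not None else 1.0
    return SummaryStats(table.reset_index(drop=True), n=n, mu_t=mu_t, sd_y=float(sd_y))


def compute_disease_summary_stats(cohort: PGxCohort) -> pd.DataFrame:
    """Main-effect-only (disease GWAS style) summary statistics.

    Returns the per-SNP marginal beta_hat on the standardized scale with a
    1-df Wald p-value, for use by the disease C+T baseline.
    """
    c = cohort if cohort.standardized else standardize(cohort)
    n = c.n
    beta_hat = c.G.T @ c.Y / n
    se = np.sqrt(np.maximum(1.0 - beta_hat**2, 0.0) / max(n - 2, 1))
    z = beta_hat / np.maximum(se, np.finfo(float).tiny)
    p = np.clip(stats.chi2.sf(z**2, df=1), np.finfo(float).tiny, 1.0)
    out = c.snp_meta[SNP_META_COLUMNS].copy()
    out["beta_hat"] = beta_hat
    out["se_beta"] = se
    out["p1df"] = p
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# summary-statistic files
# ---------------------------------------------------------------------------

def write_summary_stats(ss: SummaryStats, path: str | Path) -> None:
    """Tab-delimited table with '##' JSON header lines carrying n, mu_t, sd_y."""
    path = Path(path)
    meta = {"n": ss.n, "mu_t": ss.mu_t, "sd_y": ss.sd_y}
    cols = [c for c in SUMSTAT_COLUMNS if c in ss.table.columns]
    with open(path, "w") as fh:
        fh.write("## pgxprs-sumstats " + json.dumps(meta) + "\n")
        ss.table[cols].to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_summary_stats(path: str | Path) -> SummaryStats:
    path = Path(path)
    meta = None
    skip = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                skip += 1
                if "pgxprs-sumstats" in line:
                    meta = json.loads(line.split("pgxprs-sumstats", 1)[1])
            else:
                break
    if meta is None:
        raise ValueError(f"{path}: missing '## pgxprs-sumstats' metadata header")
    table = pd.read_csv(path, sep="\t", skiprows=skip)
    table["chrom"] = table["chrom"].astype(str)
    numeric = [c for c in SUMSTAT_COLUMNS if c in table.columns and c not in ("chrom", "ref", "alt")]
    for col in numeric:
        try:
            table[col] = pd.to_numeric(table[col], errors="raise")
        except (ValueError, TypeError) as exc:
            bad = pd.to_numeric(table[col], errors="coerce")
            line_no = int(np.flatnonzero(bad.isna() & table[col].notna())[0]) + skip + 2
            raise ValueError(f"{path}: malformed numeric value in column "
                             f"'{col}' at line {line_no}") from exc
    key = table["chrom"].astype(str) + ":" + table["pos"].astype(str)
    if key.duplicated().any():
        dups = key[key.duplicated()].tolist()
        raise ValueError(f"{path}: duplicated SNP id(s): {dups}")
    return SummaryStats(table, n=int(meta["n"]), mu_t=float(meta["mu_t"]),
                        sd_y=float(meta["sd_y"]))


def write_effect_estimates(est: EffectEstimates, path: str | Path) -> None:
    out = est.snp_meta[["chrom", "pos", "ref", "alt"]].copy()
    out["beta_est"] = est.beta_est
    out["alpha_est"] = est.alpha_est
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# genotype readers / writers
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path) -> tuple[np.ndarray, pd.DataFrame]:
    """Hard-call dosages and SNP metadata from a (possibly bgzipped) VCF.

    Multi-allelic records are skipped (logged). Positions are 1-based as in
    the source file; dosage counts the ALT allele.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    rows, meta = [], []
    skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            skipped += 1
            continue
        gt = np.asarray(var.gt_types, dtype=float)  # 0/1/2, 3 = missing
        gt[gt == 3] = np.nan
        rows.append(gt)
        af = np.nanmean(gt) / 2.0
        meta.append((var.CHROM, var.POS, var.REF, var.ALT[0], min(af, 1 - af)))
    if skipped:
        logger.info("read_vcf: skipped %d multi-allelic record(s)", skipped)
    if not rows:
        return np.empty((len(vcf.samples), 0)), pd.DataFrame(columns=SNP_META_COLUMNS)
    g = np.vstack(rows).T
    return g, pd.DataFrame(meta, columns=SNP_META_COLUMNS)


_BED_MAGIC = b"\x6c\x1b\x01"
# PLINK1 2-bit codes (SNP-major): 0=hom A1, 1=missing, 2=het, 3=hom A2
_BED_DECODE = np.array([2.0, np.nan, 1.0, 0.0])  # dosage of A1 (=alt here)


def read_plink(prefix: str | Path) -> tuple[np.ndarray, pd.DataFrame]:
    """Hard-call dosages from PLINK1 bed/bim/fam; dosage counts the A1 allele."""
    prefix = Path(prefix)
    bim = pd.read_csv(prefix.with_suffix(".bim"), sep=r"\s+", header=None,
                      names=["chrom", "snp", "cm", "pos", "a1", "a2"])
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None)
    n, m = len(fam), len(bim)
    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise ValueError(f"{prefix}.bed: not a SNP-major PLINK1 bed file")
    bytes_per_snp = (n + 3) // 4
    body = np.frombuffer(raw[3:], dtype=np.uint8)
    if body.size != bytes_per_snp * m:
        raise ValueError(f"{prefix}.bed: size mismatch for n={n}, m={m}")
    body = body.reshape(m, bytes_per_snp)
    codes = np.stack([(body >> shift) & 0b11 for shift in (0, 2, 4, 6)], axis=-1)
    codes = codes.reshape(m, -1)[:, :n]
    g = _BED_DECODE[codes].T.copy()
    af = np.nanmean(g, axis=0) / 2.0
    meta = pd.DataFrame({
        "chrom": bim["chrom"].astype(str), "pos": bim["pos"].astype(int),
        "ref": bim["a2"].astype(str), "alt": bim["a1"].astype(str),
        "maf": np.minimum(af, 1 - af),
    })
    return g, meta


def write_plink(g: np.ndarray, meta: pd.DataFrame, prefix: str | Path) -> None:
    """Write hard-call dosages (ALT counts) as PLINK1 bed/bim/fam."""
    prefix = Path(prefix)
    n, m = g.shape
    fam = pd.DataFrame({
        0: [f"F{i}" for i in range(n)], 1: [f"S{i}" for i in range(n)],
        2: 0, 3: 0, 4: 0, 5: -9,
    })
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)
    bim = pd.DataFrame({
        0: meta["chrom"], 1: [f"snp{i}" for i in range(m)], 2: 0,
        3: meta["pos"], 4: meta["alt"], 5: meta["ref"],
    })
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    code_of = {2.0: 0, 1.0: 2, 0.0: 3}
    bytes_per_snp = (n + 3) // 4
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        for j in range(m):
            codes = np.array([1 if np.isnan(x) else code_of[float(x)] for x in g[:, j]],
                             dtype=np.uint8)
            padded = np.zeros(bytes_per_snp * 4, dtype=np.uint8)
            padded[:n] = codes
            packed = (padded[0::4] | (padded[1::4] << 2)
                      | (padded[2::4] << 4) | (padded[3::4] << 6))
            fh.write(struct.pack(f"{bytes_per_snp}B", *packed))


def read_genotypes(path: str | Path, format: str | None = None
                   ) -> tuple[np.ndarray, pd.DataFrame]:
    """Dispatch to the VCF or PLINK reader, inferring the format from the path."""
    p = str(path)
    if format is None:
        format = "vcf" if p.endswith((".vcf", ".vcf.gz")) else "plink"
    if format == "vcf":
        return read_vcf(path)
    if format == "plink":
        return read_plink(p.removesuffix(".bed"))
    raise ValueError(f"unknown genotype format: {format!r}")


def harmonize_alleles(ss_meta: pd.DataFrame, panel_meta: pd.DataFrame
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Match SNPs between summary stats and a reference panel.

    Matching key is (chrom, pos, sorted alleles). Strand-ambiguous A/T and
    C/G SNPs are dropped with a warning. Returns (ss_idx, panel_idx).
    """
    def key(df: pd.DataFrame) -> pd.Series:
        alleles = [",".join(sorted((r, a))) for r, a in zip(df["ref"], df["alt"])]
        return df["chrom"].astype(str) + ":" + df["pos"].astype(str) + ":" + pd.Series(alleles, index=df.index)

    ambiguous = {"A,T", "C,G"}
    ss_key = key(ss_meta)
    panel_key = key(panel_meta)
    amb_mask = ss_key.str.split(":").str[-1].isin(ambiguous)
    if amb_mask.any():
        logger.warning("harmonize_alleles: dropping %d strand-ambiguous SNP(s)",
                       int(amb_mask.sum()))
    lookup = {k: i for i, k in enumerate(panel_key)}
    ss_idx, panel_idx = [], []
    for i, (k, amb) in enumerate(zip(ss_key, amb_mask)):
        if amb or k not in lookup:
            continue
        ss_idx.append(i)
        panel_idx.append(lookup[k])
    return np.asarray(ss_idx, dtype=int), np.asarray(panel_idx, dtype=int)
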