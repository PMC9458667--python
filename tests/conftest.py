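import numpy as np
import pandas as pd
import pytest

from pgxprs.io import PGxCohort, SNP_META_COLUMNS


def make_meta(m: int, maf=0.25, spacing=2000) -> pd.DataFrame:
    return pd.DataFrame({
        "chrom": "1",
        "pos": spacing * (1 + np.arange(m)),
        "ref": "A", "alt": "C",
        "maf": np.full(m, maf) if np.isscalar(maf) else maf,
    })[SNP_META_COLUMNS]


def make_cohort(n=300, m=8, beta=None, alpha=None, beta_t=0.0, sigma=1.0,
                n_cov=2, mu_t=0.5, seed=0) -> PGxCohort:
    """Small unlinked-SNP trial cohort with known generative effects."""
    rng = np.random.default_rng(seed)
    maf = rng.uniform(0.1, 0.5, m)
    G = rng.binomial(2, maf, size=(n, m)).astype(float)
    T = (rng.random(n) < mu_t).astype(float)
    X = rng.standard_normal((n, n_cov))
    beta = np.zeros(m) if beta is None else np.asarray(beta, float)
    alpha = np.zeros(m) if alpha is None else np.asarray(alpha, float)
    g_std = (G - G.mean(0)) / G.std(0)
    y = (X @ np.ones(n_cov) + beta_t * T + g_std @ beta
         + (g_std * T[:, None]) @ alpha + rng.normal(0, sigma, n))
    return PGxCohort(Y=y, T=T, X=X, G=G, snp_meta=make_meta(m, maf))


@pytest.fixture
def toy_cohort() -> PGxCohort:
    return make_cohort(n=400, m=5, beta=[0.5, 0, 0.3, 0, 0],
                       alpha=[0, 0.4, 0.3, 0, 0], seed=11)


@pytest.fixture
def null_cohort() -> PGxCohort:
    return make_cohort(n=400, m=6, seed=5)
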