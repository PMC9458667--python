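# Methods

## Model

All estimators target the two-arm regression

    Y = Xγ + β_T·T + Gβ + (G×T)α + ε,      ε ~ N(0, σ²I),

with Y a quantitative drug response, T ∈ {0,1} randomized treatment, X
covariates, and G dosages. Throughout, Y is first residualized on [1, X, T]
and scaled to unit variance, and each genotype column is centered and scaled
to unit variance; β ("prognostic") and α ("predictive", the G×T interaction)
are therefore on the standardized scale. Weights are mapped back to dosage
scale by dividing by the column SDs and multiplying by the recorded phenotype
SD.

**Interaction-column standardization.** The summary statistics are the
inner products b̂ = X′Y/n of the standardized joint design [G, G×T]. The
interaction columns G_j·T are themselves standardized (their SD is √μ_T for
randomized T with treated fraction μ_T), so that D = X′X/n is a proper
correlation matrix. This is an internal convention: whenever weights are
applied to genotypes (the scores S_prog = Σ β̂_j G_j,
S_pred = Σ α̂_j G_j), the stored interaction weights are divided by √μ_T
(`EffectEstimates.mu_t` records the convention; simulated true effects carry
`mu_t = 1`). Prediction R² and interaction tests are invariant to this
choice, but the relative weighting of S_prog and S_pred inside S_PGx is not,
which is why the conversion is enforced in `compute_scores` rather than left
to callers.

**Joint LD.** Under standardization and T ⟂ G, the joint-design correlation
for a block with SNP correlation Σ is

    D = [[Σ, √μ_T Σ], [√μ_T Σ, Σ]],

validated against the empirical cor([G, G×T]) of simulated cohorts (tests,
tolerance 0.02 at n = 50,000, μ_T ∈ {0.3, 0.5, 0.7}). For μ_T = ½ and rare
variants this cross-correlation is the small-MAF constant √((1−f)/2). Because
reference panels are often smaller than a block, D is ridge-regularized,
(1−ε)D + εI with the smallest ε ∈ {0, 10⁻³, 10⁻², 10⁻¹} giving positive
definiteness.

**2-df joint test.** Per SNP, the p-value of (β_j, α_j) = (0, 0) is a Wald
chi-square on 2 df using the fitted 2×2 coefficient covariance of the joint
fit Y ~ G_j + G_j×T — not a sum of independent z², since the two columns are
strongly correlated. Verified against `statsmodels` Wald tests; under a
global null with m = 5000 and threshold 10⁻³ the selected count averages the
binomial expectation of 5 (acceptance suite).

## The Bayesian estimator

Per SNP, b_j = (β_j, α_j) gets the bivariate global–local prior

    b_j | σ², φ, M_j ~ MVN(0, (σ²/n) φ M_j),
    M_j = [[ψ_j, ρ_j√(ψ_jξ_j)], [·, ξ_j]] ~ W⁻¹(B_j, 2v+1),
    B_j = 4v·diag(δ_j, λ_j),  δ_j ~ G(b₁, 1),  λ_j ~ G(b₂, 1),  b₁ = b₂ = ½,

with Jeffreys p(σ²) ∝ σ⁻². The half-t hierarchy decouples the variances
(ψ_j ~ iG(v, 2vδ_j), ξ_j ~ iG(v, 2vλ_j)) from the effect-size correlation
ρ_j; one global scale φ controls overall sparsity and is **grid-tuned, not
sampled**. Note the implied correlation marginal under this inverse-Wishart
parameterization is p(ρ_j) ∝ (1−ρ_j²)^{v−1} (checked by simulation:
E[ρ²] = 1/(2v+1)).

Gibbs conditionals, per LD block with m SNPs, Ω = φ·blockdiag-structured
prior scale:

1. b | · ~ MVN((D + Ω⁻¹)⁻¹ b̂, (σ²/n)(D + Ω⁻¹)⁻¹) — Gaussian conjugacy; the
   mean reduces to the ridge estimator (D + φ⁻¹I)⁻¹ b̂ when ψ ≡ ξ ≡ 1, ρ ≡ 0,
   and to closed 2×2 forms for a single SNP (both are unit tests).
2. σ² | · ~ iG((n+2m)/2, (n/2)·max(1 − 2b′b̂ + b′Db, 0) + (n/2)·b′Ω⁻¹b);
   the max(·,0) guards against sampling noise in the data quadratic
   (Y′Y/n = 1 after standardization).
3. M_j | · ~ W⁻¹(B_j + (n/(σ²φ)) b_j b_j′, 2v+2), sampled by a vectorized
   2×2 Bartlett construction; afterwards ψ_j and ξ_j are capped at ρ_cap/φ
   (ρ_cap = 1) with ρ_j preserved — the standard numerical guard against
   collinearity-driven blow-up — and floored at 10⁻¹² so the Ω⁻¹ entries of
   fully-shrunk null SNPs stay finite.
4. δ_j | · ~ G(b₁ + (2v+1)/2, 1 + 2v(M_j⁻¹)₁₁), and λ_j analogously with
   (M_j⁻¹)₂₂.

All four conditionals are validated against a brute-force individual-level
Gibbs sampler built directly on raw data (no summary-statistic shortcut):
posterior means agree within Monte-Carlo error at m ≤ 3, n = 500, for
(φ, v) ∈ {(0.01, 2), (1, 5)}. Chains run 1000 sweeps with 500 burn-in by
default (tuning runs may use shorter chains); each block draws its RNG
stream from (seed, block index), so results are independent of execution
order and of parallelization. A diverged block (σ² overflow) contributes
zero weights and a logged failure rather than aborting the genome.

Tuning: (v, φ) are selected by two-arm validation R² over grids
v ∈ {2, 5, 10} × φ ∈ {10⁻⁴, 10⁻², 10⁻¹, 1} by default; the benchmark uses
the reduced grid v ∈ {2, 5} × φ ∈ {10⁻², 10⁻¹, 1}. Tuning runs on summary
statistics from a stratified 80/20 sub-split of the training cohort and the
winner is refit on full-training summary statistics; a k-fold scheme is
available through the nested-CV pipeline, but a single split keeps the
replicated benchmark tractable.

## Penalized estimators

One proximal block-coordinate-descent solver covers Lasso (α_mix = 1),
Group Lasso (α_mix = 0) and Sparse Group Lasso (intermediate):
groups are the per-SNP pairs b_j, the within-group update is proximal
gradient with step 1/L_j (L_j the top eigenvalue of X_j′X_j), and the
combined prox is elementwise soft-thresholding followed by group shrinkage.
Zero groups are screened by ‖soft(X_j′r, α_mix λ)‖ ≤ (1−α_mix)λ√2.
Convergence is declared on relative objective decrease ≤ 10⁻⁹ (the
objective is monotone by construction). λ grids run 50 points log-spaced
from the analytic λ_max (all-zero point; found by bisection for mixed
penalties) down to λ_max/1000, warm-started; ties in validation R² go to
the larger λ. The SGL mixing weight defaults to 0.5 with CV over
{0.05, 0.5, 0.95}. These estimators require individual-level data; no
summary-statistic approximation is attempted.

## Synthetic data

The generator emulates a PGx GWAS built on trial genotypes:

* **Genotypes** — haplotypes from thresholding a latent AR(1) Gaussian
  (decay 0.9 between adjacent SNPs, one SNP per 2 kb) at Φ⁻¹(MAF),
  MAF ~ U(0.05, 0.5), in independent blocks of 50 SNPs; dosage = two
  haplotypes. This gives monotone distance-decaying LD inside blocks and
  none across.
* **Effects** — per block k, π_k ~ Beta(P(causal), 1−P(causal)) and causal
  indicators Bernoulli(π_k): the causal fraction is genome-wide P(causal) in
  expectation but highly clustered across blocks (the Beta is U-shaped for
  small P(causal)). Causal pairs are MVN(0, Σ_k) with Σ_k diagonal (ψ, ξ)
  at the configured ψ/ξ ratio and off-diagonal ρ_k√(ψξ), ρ_k ~ U(0, 1).
  Separate-effects mode zeroes α for a random half of causal variants and β
  for the other half. When the architecture must be non-null (σ²
  calibration), draws are repeated until at least one causal variant exists.
* **Phenotypes** — Y = X·1 + β_T T + Gβ + (G×T)α + ε with five standard
  normal covariates of unit coefficient (stand-ins for the trial's clinical
  factors). σ² is solved from the treatment-arm heritability identity
  h² = var(Σ(β_j+α_j)G_j) / (var(·) + σ²) using the empirical genetic
  variance among treated subjects; control-arm and disease-cohort
  heritability are derived quantities, not targets. Realized treatment-arm
  cor²(oracle score, Y_adj) averages the configured h² within ±0.02
  (acceptance suite). Scaling all effects leaves realized h² unchanged.
* **Disease cohort** — random-mating expansion: each offspring takes one
  whole-block haplotype from each of two distinct random parents, so allele
  frequencies and within-block LD are preserved (property-tested) while the
  sample grows to n = 20,000; its phenotype uses main effects only, with
  the σ² calibrated on the PGx arm. Genotypes are standardized after
  expansion. An n = 500 reference panel for LD matrices is drawn from the
  same haplotype pool.

What this does **not** emulate: realistic human allele-frequency spectra and
long-range LD, genotyping error and missingness, population structure and
relatedness (beyond the deliberate parent-offspring structure of the
expansion), binary/survival endpoints, and covariates correlated with
genotype. Passing benchmarks therefore demonstrate correctness of the
estimators under the stated generative model, not field performance on real
cohorts.

## Benchmark problem sizes

The replicated benchmark (and the acceptance script) runs at desk scale,
chosen as the package's own defaults: m = 1000 SNPs in 20 blocks of 50,
train n = 3000 / test n = 1000 / disease n = 20,000, 20 replicates,
reduced Bayes tuning grid, 400-sweep tuning chains and 1000-sweep final
chains. Null-calibration checks use m = 5000 with 200 replicates, the
heritability check 50 replicates, the causal-count check 500.

## Numerical choices and edge cases

* Clumping ties (equal p-values) break by position then alphabetical
  alleles, making the kept set invariant to input row order; r² is computed
  on G only; cross-block r² is treated as zero.
* R² of a constant (degenerate) score is defined as 0 with a warning, so
  method comparisons never crash; the interaction LRT with a constant
  predictive score returns p = 1 with a warning.
* The "two-sided LRT" of S_pred × T is the standard 1-df chi-square LRT
  (the chi-square reference is one-tailed; the phrase mirrors the
  equivalent two-sided Wald test).
* Stratification CIs use the two-sample normal approximation; treatment
  effects are raw arm-mean differences of the adjusted phenotype.
* Monomorphic SNPs: rejected with a named error at standardization;
  dropped with a flag from reference-panel LD (identity fallback rows).
* Allele harmonization between summary statistics and panels matches on
  (chrom, pos, sorted alleles) and drops strand-ambiguous A/T, C/G SNPs
  with a warning.
* Fold assignment in nested CV is stratified by arm so every fold can
  estimate an interaction; out-of-fold scores are concatenated and
  evaluated once.
* Validation-R² ties in C+T threshold selection resolve toward the smaller
  (sparser) threshold.

## Known limitations

* The Gibbs sampler scales as the cube of the block size per sweep; blocks
  beyond a few thousand SNPs need the (provided) per-block parallelism and
  patience.
* φ is tuned by grid search only; no full-Bayes update of the global scale
  is implemented.
* Quantitative endpoints only; binary and survival responses are out of
  scope, as are trans-ethnic weights, imputation and per-variant QC.
* PLINK dosage reading covers hard calls only (2-bit bed), not dosage VCF
  fields.
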