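# Methods

`pleiofm` fine-maps putatively causal genes for many correlated phenotypes
of mixed data types in phenome-wide transcriptome-wide association studies
(TWAS). This note records the model, the sampler, the synthetic-data
design, and the numerical and design choices a maintainer would need to
know. Everything quantitative stated here is computed by the test suite or
by `scripts/acceptance.py`; nothing is quoted from external sources.

## 1. Model

### 1.1 Expression stage (reference panel)

For gene *j* with `g_j` cis-SNPs, expression in the reference panel obeys

    x_j = Z_j^R gamma_j + eps_j,      eps_j ~ N(0, sigma_j^2 I_{n1}),

with standardized dosage columns. Each SNP effect carries a spike-and-slab
prior

    gamma_d ~ I_d delta_0 + (1 - I_d) N(0, v_j^2 sigma_j^2),
    I_d ~ Bernoulli(pi),    pi ~ Uniform(0, 1),

where the indicator `I_d = 1` selects the spike (the zero component); the
scales `v_j^2` and `sigma_j^2` carry Jeffreys priors. All conditionals are
conjugate; a Gibbs sampler cycles through each SNP's collapsed
(indicator, effect) update, then `pi`, `v_j^2`, `sigma_j^2`. When no SNP
occupies the slab the Jeffreys conditional for `v_j^2` is improper and the
current value is retained for that sweep. GReX is imputed into the GWAS
cohort as `xhat_j = Z_j^G gamma_hat_j` with the posterior-mean weights
(the mean conditional on the slab is a defensible alternative; the
posterior mean is used because it is also the Bayes-optimal point
prediction under squared error), and each imputed column is standardized.

Default chain: 4,000 iterations, 2,000 burn-in, thinning 2. Genes of a
region sharing the same SNP count are fitted in one vectorised batch; the
batch path and the public per-gene API share one kernel, verified against
exhaustive enumeration of spike patterns at `g = 2` (tests).

### 1.2 Joint gene–factor stage (one region at a time)

Within a genomic region with `p` candidate genes and `q` phenotypes,

    f_l   = sum_j beta_jl xhat_j + eps_l,    eps_l ~ N(0, omega_l^2 I),
    ytilde_i' = Lambda F_i + e_i,            e_i ~ N(0, Sigma),

with a two-level indicator prior on gene effects,

    beta_jl = I_j U_jl b_jl,   b_jl | s^2, omega_l^2 ~ N(0, s^2 omega_l^2),
    I_j ~ Ber(pi1), U_jl ~ Ber(pi2),  pi1, pi2 ~ Uniform(0,1),

and a multiplicative gamma-process prior on the loadings,

    lambda_kl ~ N(0, phi_kl^{-1} eta_l^{-1}),  phi_kl ~ Ga(3/2, 3/2),
    eta_l = prod_{r<=l} vartheta_r,
    vartheta_1 ~ Ga(a1, 1),  vartheta_h ~ Ga(a2, 1) (h >= 2),  a1, a2 > 1,

so later factors are a priori more strongly shrunk. `I_j` performs
gene-level selection; `U_jl` routes an included gene to specific factors;
exact zeros `beta_jl = 0` hold whenever either indicator is off.

### 1.3 Mixed outcome types

Binary and count phenotypes enter through Pólya-Gamma (PG) augmentation.
With auxiliary `psi_ik` and

    xi_ik = 1 (binary),   xi_ik = y_ik + r_k (count),
    ytilde_ik = y_ik (continuous),  (y_ik - 0.5 xi_ik)/psi_ik (discrete),

each discrete likelihood becomes Gaussian in the linear predictor with
per-entry precision `psi_ik`; continuous columns keep their homoscedastic
variance `tau_k^2`. The count model is negative binomial with `r_k`
successes and logit link (mean `r_k exp(zeta_ik)`); `r_k` is updated by
Chinese-restaurant-table (CRT) augmentation under a Ga(1, 0.01) prior.

In the Gibbs conditional the auxiliaries are drawn from the *tilted*
distribution `psi_ik ~ PG(xi_ik, zeta_ik)` with `zeta = lambda_k' F_i`;
the untilted PG(xi, 0) is the prior, and the tilted conditional is what
makes the augmented sampler exact. For discrete columns the effective
residual precision of `ytilde` is the heteroscedastic `psi_ik`, not
`tau_k^{-2}`; `tau_k^2` applies to continuous columns only.

### 1.4 Posterior summaries and selection

Factor-specific posterior inclusion probabilities are
`PIP_jl = P(beta_jl != 0 | data)` and the omnibus probability is the union
`PIP_j = P(exists l: beta_jl != 0 | data)`. Genes are selected by Bayesian
FDR: for threshold `z` the selected set is `{j : PIP_j >= z}` and
`BFDR(z)` is the mean of `1 - PIP` over it; the reported threshold `z*`
is the smallest `z` with `BFDR(z) <= alpha` (maximising discoveries).
Selecting genes *above* the threshold is the only reading consistent with
controlling the false-discovery rate of the *selected* set; the
factor-specific variant applies the same operator within each factor
column (separate thresholds per factor by default).

Factor label and sign are not identified. Before computing factor-indexed
summaries, every stored draw's loading columns are greedily matched (by
absolute inner product, with sign flips) to the last burn-in draw. The
omnibus PIP is computed on unaligned draws since the union event is
invariant to column relabelling.

## 2. Gibbs sampler

One systematic sweep draws, in order: `psi` (PG, tilted) and the
transformed response; `F_i` rows (batched multivariate normal, precision
`Omega^{-1} + Lambda' D_i Lambda` with `D_i` mixing `1/tau^2` and `psi`);
`Lambda` rows; `phi`; `vartheta` (hence `eta`); `tau^2` (continuous
columns); the gene block `(I_j, U_j., b_j.)` per gene — indicators drawn
with the effect analytically marginalised (collapsed), then the effect
redrawn, which avoids sticky joint states; `pi1, pi2` (Beta); `s^2` and
`omega_l^2` (inverse gamma); `r_k` (CRT). The `r` update marginalises
`psi`, which is valid because `psi` is redrawn from its full conditional
at the start of the next sweep before anything else conditions on it
(partially-collapsed Gibbs ordering).

Correctness is established by (i) exhaustive-enumeration oracles for the
spike-pattern and gene-inclusion posteriors on tiny instances, (ii) a
conjugate closed-form check of the effect update with indicators forced
on, (iii) closed-form PG moment identities and a quadrature oracle for a
1-covariate logistic posterior built only from the augmentation
primitives, and (iv) a successive-conditional (Geweke-style) test of the
full sampler at tiny dimensions. The Geweke run uses proper
weakly-informative hyperpriors (the Jeffreys defaults cannot be
forward-sampled), `a1 = a2 = 8`, and bounded (tanh) tracked statistics:
raw squared loadings have non-finite prior variance under the
Ga(3/2, 3/2) local-precision prior, and with diffuse loadings a large
`lambda` on a count column generates huge counts whose PG precisions pin
the chain in a slowly-escaping region — both of which would corrupt the
z-statistics without touching the correctness of the conditionals.

### 2.1 Adaptive factor truncation

During burn-in only, with probability `exp(-alpha0 - alpha1 t)` at sweep
`t` (defaults `alpha0 = 1`, `alpha1 = 5e-4`): columns of `Lambda` whose
entries are all negligible are removed (together with the matching
columns of `U`, `b`, `B`, `F`, `phi`, `vartheta`, `omega^2`; `eta` is
recomputed), and if no column is negligible and `m < m_max` one column is
appended from the prior. At least one column is always retained.
"Negligible" means below `max(eps, 3 / sqrt(n2 * dbar_k))` per phenotype,
with `eps = 1e-2`: the second term is the posterior noise floor of a
loading, and a fixed absolute threshold below that floor would never
prune (the truncation would only ever grow). Truncation is frozen after
burn-in so stored draws share one `m` and factor-indexed summaries are
well defined.

### 2.2 Priors: one deliberate deviation

`s^2` (the slab scale of gene effects) uses a weakly-informative proper
IG(2, 1) prior by default rather than a Jeffreys prior. Under a global
null no gene is active, a Jeffreys-scaled `s^2` is then unidentified, and
the `(b, s^2)` subchain drifts as an improper random walk whose
small-`s^2` excursions collapse the spike/slab Bayes factor toward 1
(the Bartlett–Lindley phenomenon) and inflate null PIPs — in desk-scale
experiments, to the point of spurious selections. IG(2, 1) is natural
here because GReX columns are standardized and factors have roughly unit
variance, so `s^2 ~ 1` is the right scale; `ChainConfig.s2_prior = (0, 0)`
restores Jeffreys. `omega_l^2`, `tau_k^2` and `v_j^2` keep Jeffreys
priors: they are informed by `n` data terms and remain well identified.

### 2.3 Other numerical choices

* PG sampling uses the sum-of-gammas series truncated at `trunc` terms
  plus a single gamma variate moment-matched to the analytic tail, so the
  first two moments are exact at any truncation; entries with shape
  `b >= 170` use a normal approximation. The standalone sampler defaults
  to 200 terms; the Gibbs sweep uses 6–8, validated distributionally
  against a 500-term reference (KS) and by the quadrature oracle.
* The CRT total is drawn as binomials over table positions `t <= 64`; the
  aggregate of positions beyond 64 (each with success probability below
  `r/(r+64)`) is drawn as one Poisson with the exact mean obtained from
  the digamma identity, keeping the update O(n) for arbitrarily large
  counts.
* Initialisation: SVD of a Gaussianised phenotype proxy (`log1p` for
  counts, centering elsewhere) for `Lambda` and `F`; ridge regression of
  `F` on GReX for `b`; method-of-moments variances; all indicators on.
* Degenerate inputs: zero-variance SNP columns are dropped with a warning
  before fitting; all-zero weight vectors and constant imputed GReX
  columns are excluded from the GReX matrix with a warning; missing
  phenotype entries are rejected (the model assumes complete Y);
  `r_k` is clipped to `[1e-3, 1e4]` (the upper end is already effectively
  Poisson).
* Covariates, when given, are residualised out of GReX and continuous
  phenotype columns; discrete phenotypes are left unadjusted (a known
  limitation of the linear residualisation).

### 2.4 Chain profiles

The model's defaults are long chains (10,000 sweeps, 5,000 burn-in,
thinning 5, `m_init = min(q, 15)`, `m_max = q`) appropriate for real
analyses. The simulation-study driver and the acceptance script use a
desk-scale profile sized to the reduced problems they generate: 220
sweeps (120 burn-in, thinning 1, 100 stored draws), `m_init = m_max = 6`
(8 for the 50-phenotype recovery study), PG truncation 6, and 800/400/2
expression chains. These are analysis choices for small, warm-started
problems — the null studies mix within tens of sweeps — and all settings
are exposed in `ChainConfig` / `StudyProfile`.

## 3. Synthetic-data generator

The generator reproduces the structure of a phenome-wide TWAS simulation
with full knowledge of the truth. Defaults: reference panel `n1 = 250`,
GWAS `n2 = 5000`, 10 regions x 10 genes x 10 cis-SNPs, `q = 50`
phenotypes, `m` in {1, 3, 5} latent factors, heritability `h2` in
{1%, 3%, 5%}, and 1–2 causal genes per region (count drawn uniformly).

* **Genotypes.** Two latent haplotypes per individual follow an AR(1)
  Gaussian along the region's SNPs (lag-1 correlation `ld_rho`, default
  0.5, so LD spans gene boundaries); each is thresholded at its SNP's
  minor-allele-frequency quantile (MAF ~ Uniform(0.05, 0.5), shared
  between reference and GWAS panels) and summed to a dosage in {0, 1, 2},
  then column-standardized. Realized dosage LD is validated against
  numeric integration of the thresholded bivariate normal.
* **Expression.** Three of the 10 cis-SNPs per gene are causal with
  N(0, 1) effects rescaled so cis-SNPs explain `h2_expr = 0.3` of
  expression variance (residual `1 - h2_expr`). Both sparsity level and
  `h2_expr` are tunable; the defaults are ordinary values for cis-eQTL
  architectures.
* **Phenotypes.** True GReX `Z_j^G gamma_j` (standardized) drives each
  factor's genetic part, scaled to variance `3 h2` per factor; factor
  noise brings factors to unit variance. Scenario 1 (homogeneous) gives
  every factor the same causal genes; scenario 2 (heterogeneous) assigns
  each causal gene to exactly one factor (round-robin, so the sets
  differ); scenario 3 (null) sets all gene effects to zero. Each
  phenotype loads on at most two factors (unit-norm N(0,1) loadings;
  every factor gets at least one phenotype). A per-phenotype residual
  variance is then *solved* so the phenotype-level GReX-explained
  fraction equals `h2` exactly in the sample — on the observed scale for
  continuous phenotypes and on the latent linear-predictor scale for
  binary (logistic) and count (negative binomial, `r = 5`, intercept
  −1.5) phenotypes, where the observed-scale fraction has no closed form.
  The factor-level `3 h2` headroom makes the solved residual variance
  positive except in rare antagonistic two-factor loadings, which are
  floored at 0.05.

What the generator does *not* emulate: real LD patterns from reference
haplotypes, population structure and relatedness, imputation uncertainty
in the weights, case-control ascertainment, and phenotype missingness.
Passing tests therefore demonstrate correctness of the machinery and
calibration under the stated generative design, not performance on any
real cohort.

## 4. Study drivers and metrics

`run_replicate` executes the full pipeline (train weights per region,
impute GReX, fine-map each region, pool PIPs across regions) and scores
it against the truth: ROC AUC of omnibus PIPs (validated against a
Mann–Whitney computation), true/false positives and false-discovery
proportion at BFDR 0.1, and an F-score for recovery of the sparse loading
support. A loading is called nonzero when its posterior probability of
exceeding 0.01 in absolute value is above 0.5, after greedy matching of
estimated to true factor columns. `null_fdp_study` runs the global-null
design (no causal genes anywhere; every selection is a false positive)
and reports the mean false-discovery proportion across replicates —
the package's headline calibration check, recomputed from scratch by
`scripts/acceptance.py` at `n1 = 250`, `n2 = 1000`, 5 regions x 10 genes,
`q = 20` mixed-type phenotypes, 50 replicates.

Region screening for real analyses combines univariate TWAS p-values
(OLS / logistic / negative-binomial Wald tests via statsmodels) across
phenotypes with Fisher's method and keeps LD blocks containing at least
one gene below a genome-wide threshold (default 1e-8). Phenotype
correlation makes the combined p-values screening scores rather than
calibrated tests; the joint model performs its own inference on the
selected regions.

## 5. Known limitations

* Summary-statistic input, multi-tissue weight training, variational
  inference, credible-set construction and cross-region joint modelling
  are out of scope.
* Categorical phenotypes must be pre-expanded to binary dummies.
* Factor-specific conclusions depend on the greedy post-hoc alignment;
  in weakly-identified factor spaces the per-factor PIPs are less stable
  than the omnibus PIP (which needs no alignment).
* The BFDR operator controls a Bayesian, model-based quantity; its
  frequentist FDR behaviour is verified empirically only under the
  generator's null design.
* With very small regions (few genes), the Uniform(0,1) priors on the
  inclusion probabilities leave null PIPs around 0.3–0.5; selection at
  stringent `alpha` still behaves correctly because the BFDR of such sets
  stays high, but single-gene PIPs should not be over-read.
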