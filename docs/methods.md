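# Methods

## The model

Phenotype records are line means, one per line per environment (cycle).
Stacking them as a records × traits matrix `Y`, the model is

    Y = 1 μ' + X_E β_E + Z_L b1 + Z_LE b2 + e

* `b1 ~ MN(0, G, Σ_T)` — line main effects, matrix-normal with row (line)
  covariance `G` and column (trait) covariance `Σ_T`;
* `b2 ~ MN(0, I_I ⊗ G, Σ_TE)` — genotype-by-environment effects,
  independent across environments, `G`-correlated within;
* `e` — residual rows i.i.d. `N(0, R)` across records;
* priors: `f(μ, vec β_E) ∝ 1`; `Σ_T ~ IW(ν_T, S_T)`, `Σ_TE ~ IW(ν_TE,
  S_TE)`, `R ~ IW(ν_R, S_R)`.

The trait covariances of the main and interaction effects are kept as two
separate sampled matrices with identical default priors; analyses that
want them tied can pass the same fixed matrix for both.

`G` is the VanRaden (method 1) relationship matrix, `W Wᵀ / (2 Σ_j p_j
(1 − p_j))` with `W` the dosage matrix column-centred at `2p_j`.  Allele
frequencies are computed on the combined two-cycle panel, since one `G`
must cover training and testing lines together.  Note the diagonal of
this matrix averages near 1 only for a panel in Hardy–Weinberg
equilibrium; fully inbred lines run higher (the worked 2-line example in
the tests has diagonal 2, which is `1 + F` at `F = 1`).

### Gibbs sampler

All updates are full conditionals:

1. **Missing cells** (including the wholly-masked testing lines of the
   cross-validation) are data-augmented from their conditional Gaussian
   given the observed cells of the same record.
2. **Fixed effects** are parameterised as per-environment trait-mean
   vectors (flat prior ⇒ Gaussian conditional) and reported as `μ` =
   first-environment mean plus corner-constrained `β_E`.  Correlation
   metrics are shift-invariant, so the constraint choice is cosmetic.
3. **`b1`**: `G + λI` (ridge `λ = 1e-6`, configurable, logged) is
   eigendecomposed once; in the rotated basis the conditional factorises
   into independent per-line T×T Gaussians, updated with batched
   linear algebra.  This exploits `Z_Lᵀ Z_L = I`, i.e. one record per
   line — exactly the two-cycle trial structure.  A line phenotyped in
   several environments is rejected with a clear error; generalising the
   sampler to replicated incidence would require a different (slower)
   update and is a known limitation.
4. **`b2`** is sampled per environment over that environment's lines with
   prior `MN(0, G_sub, Σ_TE)` — the marginal of the Kronecker prior for
   the only blocks any two-cycle prediction uses.
5. **Covariances** by conjugacy: `Σ_T | b1 ~ IW(ν_T + J, S_T + b1ᵀ G⁻¹
   b1)` and analogously for `Σ_TE` and `R` (residual scatter over all,
   augmented, records).

Defaults: `ν = n_T + 2`, scale `0.5·I` (weak, centred near variance 0.5
— sensible for traits analysed on roughly unit scale; rescale your
phenotypes or the priors otherwise); 12,000 sweeps, 2,000 burn-in, thin
5.  Tests and the bundled studies use shorter chains (300–20,000 sweeps,
stated per test) sized to the problem at hand; effective sample sizes
are reported (Geyer initial-monotone-sequence estimator) but not
enforced.  Every fit is reproducible from its integer seed; nested seeds
are derived with `numpy` `SeedSequence`.

Predictions for unphenotyped lines are posterior means of
`μ + β_E[env] + b1 + b2[env]`, with the breeding-value part `b1 +
b2[env]` exposed separately.  Heritability is estimated on the whole
dataset from the single-trait model as the posterior mean of `σ_g² /
(σ_g² + σ_gE² + σ_e²)`; by default the G×E variance counts as
non-heritable (it does not transfer across seasons), and a flag gives
the narrower `σ_g²/(σ_g²+σ_e²)` reading.

### Oracle

`closed_form_gblup` solves the fixed-variance mixed-model problem exactly
(GLS intercept, then `σ_g² G V⁻¹ (y − μ̂)`), and is cross-checked against
a second closed form.  The sampler with variances pinned must reproduce
it; this is the package's primary correctness gate for the MCMC.

## Accuracy estimators

With `Y = μ + g + ε` and predictions `ĝ` built only from training-cycle
information, `Cov(ĝ, ε) = 0` gives `Cor(ĝ, Y) = Cor(ĝ, g)·√h²`.  Hence:
PC1 = `Cor(y, ĝ)` (predictive ability), PC2 = PC1/√h², PC4 = PC3·√h²,
and PC3 from the bivariate genomic model of the pair (observed,
predicted) on the testing lines:

* genetic covariance Σ (2×2) with line covariance `G`;
* residual covariance `diag(σ_eo², σ_ep²)` — the cross term is fixed at
  zero because predictions share no non-genetic information with
  held-out phenotypes;
* per retained draw, `PC3 = [σ_gop/√(σ_go² σ_gp²)]·√(ĥ_p²)` with `ĥ_p² =
  σ_gp²/(σ_gp²+σ_ep²)`; the posterior mean of the per-draw ratio is
  reported (invariant to per-draw rescaling).  When `σ_ep² = 0` this is
  exactly the genetic correlation, which is the construction's point.

**Prior for Σ: parameter expansion.**  On a testing set of a few hundred
weakly related lines, the split of the observed phenotype's variance into
genetic and residual parts is only weakly identified, and a plain
`IW(3, diag(0.5, 0.5))` prior measurably shrinks `σ_go²` (we observed
posterior means near 0.63 when the generating value was 1.0 at n = 200),
which inflates the estimated genetic correlation by ~0.1.  The sampler
therefore uses the parameter-expanded prior `Σ = Λ Ψ Λ` with `Ψ ~ IW(3,
diag(0.5, 0.5))` and `Λ = diag(λ_o, λ_p)`, `λ_k ~ N(0, 1)` — approximately
uniform on the genetic correlation — after which the variance components
are near-unbiased and the PC3 bias drops to ~+0.03 on the same
constructed-truth instances.  The prediction-side residual prior scale is
0.01: posterior-mean predictions carry almost no residual of their own.
PC2 values above 1 (finite-sample artifact) are passed through with a
warning, never clipped.

MAAPE contributes `arctan|(y − ŷ)/y|` per record; a zero observed value
contributes the limiting π/2 (the metric stays bounded; the convention is
ours, as none is standard).

## Synthetic data generator

The generator emulates a two-cycle wheat program at the scale of a real
pair of trials (defaults: 1,386 training lines, 509 testing lines, the
sizes of a 2017–2018/2018–2019 trial pair): independent biallelic
markers with frequencies uniform on `maf_range`, HW dosages, `G` from
those markers, and phenotypes assembled exactly per the model above.
Cycle-1 lines are phenotyped only in environment 1 and cycle-2 lines only
in environment 2; the realised total genetic value `g = b1 + b2` of every
line in its own environment is recorded, making true accuracy
`Cor(g, ĝ)` computable.

What it deliberately does **not** emulate: linkage disequilibrium (the
model consumes only `G`, and finite marker sampling already produces
relatedness noise; a few hundred to a few thousand independent loci play
the role of the effective dimension of a dense, LD-structured GBS panel),
GBS missingness patterns, selection between cycles, or plot-level
replication (records are line means).  Passing tests therefore show the
estimators behave as claimed *under the model's own assumptions* —
model-misspecification robustness on real data is a separate question.

Implied heritability: `h²_t = Σ_T[t,t] / (Σ_T[t,t] + Σ_TE[t,t] +
R[t,t])`, consistent with the estimator's default denominator.

## Cross-validation design

Each evaluation trains on the full previous cycle plus a random 10% of
the current cycle (it anchors the current season's environment effect)
and predicts the remaining 90% with *all* traits masked.  Five 10%
selections cannot tile the cycle, so the five "folds" are five
independent random draws — replicate evaluations of the same deployment
rule — and both model arms share them, making the multi- vs single-trait
comparison paired.  The augment size is round-half-up (`509 → 51/458`).
Heritabilities for the PC2/PC4 corrections are estimated once per trait
from the whole dataset, not per partition.

## Numerical choices and degenerate inputs

* PSD square roots via eigendecomposition with negative-eigenvalue
  clipping at 0 (tolerance 1e-8 relative) — zero covariance matrices are
  legal generator inputs (noiseless limits).
* A 1e-13 jitter stabilises batched Cholesky factorisations of nearly
  singular conditional covariances.
* Zero-variance inputs to correlations raise errors rather than NaN;
  fully missing markers must be filtered before imputation; an all-marker
  QC wipeout names the binding filter.
* EM imputation is soft-impute style (rank-k SVD refill of originally
  missing cells, k default `min(10, dims−1)`, clipped to [0, 2]); mean
  imputation is the default for speed since downstream `G` is
  insensitive at these tolerances.

## Calibration and recovery studies (what the numbers mean)

`run_calibration_study` replicates the deployment setting (default 30
replicates of 500/200 lines at h² = 0.5 on unit phenotypic scale) and
reports per-replicate PC1–PC4 against the known true accuracy.  The
expected picture, which the acceptance tests assert: mean PC1 ≈ true
accuracy·√h² (underestimation), mean PC2 and PC3 within ±0.05 of the
true accuracy.  Parameter recovery is assessed as the *mean* posterior
estimate over replicate simulations, because a single 400-line
realisation carries ~0.1 of realisation noise in h² (verified against a
profile-likelihood oracle that lands where the posterior lands, away
from the generating value).

## Known limitations

* One phenotype record per line (no replicated or multi-environment
  incidence per line).
* Gaussian traits only; no REML/ML alternative (the Bayesian route was
  chosen precisely because multi-trait likelihood fits converge poorly).
* PC3's bivariate model omits environment fixed effects (testing lines
  sit in one environment; its two intercepts absorb the shift).
* The generator's independent-marker assumption understates long-range
  relatedness structure of real panels; treat absolute accuracy values
  from simulations as indicative, not forecasts for a given program.
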