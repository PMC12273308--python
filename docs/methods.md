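# Methods

This note documents the models implemented in `rumenpred`, the numerical
choices behind them, the design of the synthetic-data generator, and what the
package's tests do and do not establish about real data.

## Phenotype adjustment

Raw phenotypes are adjusted once, before any mixed-model fitting, by ordinary
least squares on the fixed effects: birth/rearing-rank class, dam-age class,
contemporary group (flock × birth year) and the birthday-deviation covariate.
The residuals `y_adj = y − X β̂` are the working phenotypes everywhere
downstream, so all mixed models carry an intercept as their only fixed effect.
Class factors enter as dummy columns with the first level dropped; a
rank-deficient design is rejected with the collinear columns named (via
pivoted QR). Adjusting on the full sample once (rather than within training
folds) mirrors the two-stage practice of the motivating analyses; the
adjustment is idempotent, so re-running it on residuals is a no-op.

A caveat this creates: the contemporary-group classes absorb between-group
genetic differences, which deflates downstream heritability estimates by a few
thousandths — visible in the simulator calibration below.

## Microbiome features

Tag counts `c_ij` (samples × tags) are made comparable by one of two
transforms:

* **log₁₀ proportion**: `t_ij = log10((c_ij + 1) / (R_i + p))` where `R_i` is
  the sample's total count and `p` the number of tags. The denominator is the
  row total *after* the +1 increment, which is the only reading under which
  each row of `10^t` is a probability vector.
* **CLR**: `v_ij = ln(c_ij + 1) − mean_j ln(c_ij + 1)`; rows sum to zero.

Either transform is followed by column standardization to mean 0, variance 1
(sample, n−1 denominator) **within each rumen cohort** — the set of animals
sharing flock, birth year, measurement window and sequencing batch — which
removes cohort-level technical and environmental shifts. Columns constant
within a cohort are set to 0 there; cohorts of one sample cannot be scaled and
are an error.

## PCA

PCA is a thin SVD of the column-centered standardized features (columns are
not re-scaled; they already have unit within-cohort variance). Because
within-cohort standardization forces all column means to zero, centering is a
no-op and the full-rank score kernel coincides exactly with the tag kernel
(below). Component signs follow a deterministic convention (largest-magnitude
loading element positive), so results are reproducible across platforms.
`threshold_map[t]` gives the smallest J whose cumulative variance fraction
reaches `t`; the conventional grid is {0.25, 0.5, 0.75, 0.95, 1.0}. PCA is
computed on the combined train-and-test features by default — the trait never
enters the decomposition — with a train-only option for stricter protocols.

## Kernels

* `grm_vanraden` — VanRaden method 1: `G = ZZ' / (2 Σ p_k(1−p_k))` with
  `Z = dosages − 2p`, allele frequencies from the provided samples,
  monomorphic SNPs dropped. Used by the REML models.
* `grm_scaled` — `G = XX'/K` with centered, unit-variance genotype columns.
  Used inside NN-GBLUP layer 1, matching that model's definition. The two
  conventions differ only in per-SNP weighting; on common-variant panels
  their off-diagonals correlate > 0.99, and both are kept because each model
  is defined with its own convention.
* `microbiome_similarity` — row-cosine of the standardized features, diagonal
  exactly 1. With zero column means this equals the Pearson correlation of
  sample profiles. Defined this way so that the 100%-variance PC kernel
  equals the full-tag kernel *by construction*.
* `pc_kernel(J)` — `S_J S_J'` from the first J PC scores, normalized to
  correlation form `D^{-1/2} K D^{-1/2}`.

All kernels are symmetric PSD up to numerical jitter. A small ridge
(10⁻⁶ × mean diagonal of the matrix being factorized) is added before any
downstream inversion, never stored in the kernel itself.

## REML

Variance components are estimated by restricted maximum likelihood with the
intercept as the only fixed effect.

* **Single kernel** (exact): in the kernel eigenbasis the restricted
  likelihood profiles to a one-dimensional function of the variance ratio
  λ = σ²_k/σ²_e; a coarse grid over log λ ∈ [−12, 12] brackets the optimum and
  bounded scalar minimization (xatol 10⁻¹²) refines it. The λ = 0 boundary is
  checked explicitly, and estimates below 10⁻⁸ × var(y) are reported as 0.
* **Two kernels**: average-information updates with step-halving when the
  restricted likelihood would decrease, and an expectation-maximization step
  when the AI step leaves the parameter space; convergence at
  |Δ logL| < 10⁻⁶ and relative parameter change < 10⁻⁶, at most 200
  iterations (a non-converged fit is returned flagged, with a warning).

Microbiability is `σ²_m/(σ²_m + σ²_e)`; heritability is σ²_u over the total
variance of the fitted model. BLUP for any sample set uses kernel
cross-blocks: `û_target = σ²_u K[target, train] V⁻¹ (y_train − μ̂)` with `V`
built on the training block and μ̂ the GLS mean, so unphenotyped animals are
predicted from kernels built once on all samples.

## NN-GBLUP

Both layers are conjugate Gibbs samplers with scaled-inverse-χ² priors on all
variances (ν = 4; scale set so the prior mode equals half the observed
variance of that sampler's response — for the layer-2 weight variance, half
the phenotype variance divided by the mean squared score scale). Chains
default to 6000 iterations, 1000 burn-in, thinning 5 — enough for the
posterior means used here — and `McmcSettings.paper_scale()` switches to the
long published schedule (60000 / 10000 / 10).

* **Layer 1** samples `(μ_j, g_j, σ²_{g_j}, σ²_{ε_j})` per PC in the
  eigenbasis of the scaled GRM, where `g = Uγ` has independent scalar
  conditionals (`γ_i ~ N(0, d_i σ²_g)`); each sweep is O(n). The prior on
  marker effects is applied at the genetic-value level,
  `g_j ~ N(0, G σ²_{g_j})` — the standard GBLUP equivalence; marker effects
  are back-solved only when the marker-route GEBV is requested. The GRM
  eigendecomposition is computed once and shared by all J samplers; per-PC
  seeds derive deterministically from the master seed and PC index, so
  results are independent of execution order and thread count.
* **Layer 2** is Bayesian ridge regression of `y_adj` on the J PC scores. The
  design is rotated into the eigenbasis of `S'S`, where `B'B` is diagonal and
  the weight conditional factorizes into independent scalars (the iid normal
  prior is rotation invariant), making each sweep an exact joint draw.
* **Prediction**: `GEBV = X_s Ŵ⁽⁰⁾ ŵ⁽¹⁾` with `Ŵ⁽⁰⁾ = X_s'(X_s X_s')⁺ ĝ`;
  the kernel route `ĝ_target = G[target,train] G[train,train]⁻¹ ĝ_train`
  evaluates the same linear map and is the default. Genotype scaling uses the
  training-set statistics. Because the omics layer is fully observed and the
  activation linear, the layers decouple and sequential fitting equals joint
  fitting; this is a property of the model, asserted by construction.
* **Diagnostic mode**: `gibbs_gblup_single(..., fix_variances=(σ²_g, σ²_ε))`
  holds the variances fixed, in which case the posterior mean of g is exactly
  the BLUP at those variances — the oracle the tests check to 0.02 RMS. The
  *full* sampler's posterior mean differs from the REML plug-in BLUP in
  shrinkage scale (not direction) whenever n is small, because the variance
  posterior is wide and right-skewed; at n = 50 the difference is ~0.15 RMS
  at correlation 0.997. This is expected behavior, not a defect.

**Training modes.** `train-only` (default) fits layer 1 on training samples
only. `transductive` also conditions layer 1 on the test animals' observed PC
scores — their phenotypes are never used. The transductive mode corresponds
to the evaluation setting in which test animals have genotype and microbiome
data but missing phenotypes, and it is where the NN-GBLUP's advantage over
GBLUP materializes: with observed microbiomes, the genetic values of the
heritable community axes for test animals are essentially read off rather
than predicted from SNPs. Under `train-only` at the sample sizes simulated
here, NN-GBLUP and GBLUP are statistically indistinguishable.

## Validation

* `split_by_group`: deterministic membership split (e.g. train on birth years
  2014–2015, test on 2016). Samples with a missing group value are excluded
  with a warning.
* `cohort_kfold`: within each cohort a seeded permutation is dealt round-robin
  into k sub-groups (sizes differ by at most 1; a cohort of 10 under k = 5
  yields five pairs); fold i's test set is the union of sub-group i across
  cohorts, so every sample is tested exactly once. Round-robin dealing, not
  independent assignment, is what guarantees near-equal sub-group sizes.
* Accuracy `r` is the Pearson correlation of adjusted phenotypes with GEBVs,
  SE `(1 − r²)/√n`. Dispersion bias is the slope of `y_adj` on GEBV (1 =
  correctly dispersed); its SE defaults to the same regression's slope SE,
  with the reversed-regression variant (slope SE of GEBV on `y_adj`) behind
  `paper_bias_se=True` — both are exposed because the published procedure
  reports the reversed regression, which is likely a transcription slip, and
  no guess is baked in. K-fold results are pooled as means with the
  across-fold SD as SE. The slope is a ratio statistic: it is unbiased in
  expectation under a correctly specified model but needs adequate signal
  (accuracy, test-set size) for its replicate distribution to concentrate;
  with weak predictors single-split slopes are heavy-tailed.

## The simulator

`simulate_population` generates a complete study — genotypes, tag counts,
phenotypes, fixed-effect structure and ground truth — with the causal
structure the estimators assume. Defaults define the reference study scale:
n = 1000 animals, K = 2000 SNPs, p = 3000 tags, 3 birth years × 2 flocks
(6 cohorts ≡ contemporary groups).

1. **Genotypes**: allele frequencies ~ U(0.05, 0.95); paternal half-sib
   families of 10, nested within birth year (each sire serves one lamb crop).
   Family structure emulates flock pedigrees and, by raising the off-diagonal
   variance of G, lowers the REML heritability sampling SD from ~0.065 to
   ~0.045 per replicate; nesting within year means a year-based train–test
   split carries no family links across the split.
2. **Community axes**: R = 40 genetic factors `T = X_c B` (standardized).
   Half the tags are heritable: their latent values load on the factors with
   per-tag heritability 0.8, plus cohort effects (SD 0.5) and idiosyncratic
   noise; the other half are cohort + noise only. With 40 axes the
   25%-variance threshold maps to ~23 of ~990 components — the same order as
   real tag data — and no single axis dominates the spectrum.
3. **Counts**: softmax of (baseline log-abundance + latent), library sizes
   log-normal (median 3×10⁵, σ 0.3), gamma–Poisson (negative binomial,
   dispersion 10). Mean tag depth ~100 reads.
4. **Mediated effect**: the realized transformed, cohort-standardized
   features `Z` (computed with the package's own preprocessing) are combined
   with one iid weight draw over all tags — i.e. the mediated effect is a
   typical draw under the microbiome similarity kernel, which makes the
   microbiability estimand equal the mediated variance fraction without
   spectral bias. Its host-genetic part is the projection onto the realized
   factor scores (exactly X-linear); the measured projection share is debiased
   for the chance capture of environmental content in an (R+1)-dimensional
   subspace, and shrunk only if it would overrun the heritability budget
   (cap 0.9·h²/m²).
5. **Calibration**: the mediated effect is rescaled to hit the target
   microbiability exactly; the direct genetic effect `X_c γ` is scaled so
   direct + mediated-genetic variance equals the target heritability; the
   residual takes the remainder. Scaling is empirical on the realized sample
   because the count-level nonlinearity admits no closed form. Direct and
   residual draws are *not* orthogonalized against the factor scores or the
   mediated effect: forcing exact in-sample orthogonality makes train- and
   test-block covariances cancel, which anti-correlates chance effects across
   validation splits (and, against dozens of factor directions, reads as
   anti-genetic structure to REML).
6. **Fixed effects**: contemporary-group, birth/rearing-rank and dam-age
   class effects plus a birthday-deviation covariate, all removed by the
   standard adjustment.

Presets anchor the variance targets to published trait estimates:
`methane` (h² = 0.18, m² = 0.47), `rfi` (h² = 0.33, m² = 0.70), and `co2`
(h² = 0.05, m² = 0) for a trait the microbiome does not mediate and for which
published prediction accuracies are near zero for genomic and
microbiome-aware models alike — which requires low heritability, not merely
zero mediation. `custom` requires explicit fractions.

**Calibration accuracy** (60 replicates per preset, two independent seed
batches, full pipeline): mean ĥ² 0.181 / 0.331 against targets 0.18 / 0.33;
mean m̂² 0.480 / 0.717 against 0.47 / 0.70; per-replicate SDs ~0.045 (ĥ²) and
~0.065 (m̂²). The small positive m̂² drift (~+0.015) is family-block leakage
of direct genetic variance into the microbiome kernel (the same mechanism
gives the non-mediated preset a mean m̂² of ~0.013 instead of 0); the small
negative pressures on ĥ² are contemporary-group absorption and
sample-frequency GRM shrinkage. These are properties of the estimators under
realistic structure and are left visible rather than tuned away.

## What the synthetic studies do and do not show

The simulator reproduces the *mechanisms* the method relies on — heritable,
PCA-compressible community axes; kernel-spread microbiome effects; cohort and
family structure; count-level noise — at a scale one CPU handles in seconds
per replicate. It does not attempt real taxonomic composition, strain
phylogenies, linkage disequilibrium, read-level sequencing artifacts, or
genotype-by-environment interaction. Passing tests therefore demonstrate that
the estimators recover what they claim *under the assumed causal structure*,
not that any particular real dataset satisfies that structure. In particular,
the NN-GBLUP's measured advantage is conditional on genuinely
microbiome-mediated genetic variance and on microbiome availability for
prediction candidates (the transductive setting); for traits without
mediation the model neither gains nor materially loses accuracy.

## Problem sizes used by the automated checks

Parameter recovery runs 10 replicates per preset at the reference scale
(n = 1000, K = 2000, p = 3000). The model-comparison experiments run 20
replicate year-split studies per preset at the same scale with the desk-scale
chain settings. Oracle equivalences use small exact fixtures (n = 4–50, with
one 200k-iteration chain), and the calibration checks for dispersion bias use
50 replicates at n = 300. These sizes were chosen so the whole suite
exercises every path end-to-end in a few minutes on a single core.
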