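# Methods

This note documents the models and procedures implemented in `iadep`,
the choices made where the design was genuinely open, and what the
synthetic benchmarks do and do not demonstrate.

## The prediction problem

Genomic prediction regresses a quantitative phenotype *y* on a panel of
biallelic SNP genotypes so that individuals with known genotype but
unmeasured phenotype can be ranked. The classical decomposition of the
genotypic value is

    G = A + D + I

with *A* the sum of per-locus additive effects, *D* the within-locus
dominance deviations and *I* the between-locus (epistatic) interaction
deviations. The package's central idea is to hand the network this
decomposition explicitly through a per-SNP embedding built from two
association scans.

## SNP embedding

Genotypes are dosage-coded {0, 1, 2} and recoded to the signed states
{−1, 0, +1} (dosage − 1), so the heterozygote occupies state 0. Each
SNP then embeds as a 3-vector:

| state | channel 1 (additive) | channel 2 (dominance) | channel 3 (interaction) |
|-------|----------------------|-----------------------|-------------------------|
| +1    | −log₁₀ p_GWAS        | 0                     | −log₁₀ p_LIT            |
| 0     | 0                    | 1                     | −log₁₀ p_LIT            |
| −1    | +log₁₀ p_GWAS        | 0                     | −log₁₀ p_LIT            |

where p_GWAS is a per-marker additive-association p-value and p_LIT a
per-marker latent-interaction p-value. Choices made here:

* **Log base 10** — the Manhattan-plot convention; only "−log" is
  standard in the field and any base is a monotone rescaling.
* **p floor** — p-values are clipped to 1e−300, i.e. −log₁₀ p ≤ 300,
  so the embedding is always finite.
* **Heterozygote orientation** — mapping {0,1,2} dosage to {−1,0,+1}
  by subtracting 1 is a declared convention: the heterozygote must be
  the state carrying the dominance indicator, and flipping a marker's
  allele orientation only negates its additive channel, which the
  architecture treats symmetrically.
* **Frozen embedding** — the embedding is a fixed initialization, not
  a trained parameter. A `trainable_embedding` switch exists for
  experimentation (it promotes the per-(marker, state) table to a
  parameter initialized at the values above) and is off by default.

Two ablation encodings are provided for comparison: `one_hot`
([1,0,0]/[0,1,0]/[0,0,1] for states +1/0/−1) and `raw` (the
single-channel signed value), which deliberately destroy the
between-marker information the embedding carries.

## The association priors

`gwas_scan` is a vectorized single-marker OLS: the two-sided t-test on
the slope of phenotype on signed dosage. An optional `mixed` mode first
fits a single genetic variance component on the genomic relationship
matrix by REML, rotates phenotype and genotypes into the GRM eigenbasis,
whitens, projects out the (no-longer-constant) whitened intercept and
runs the same test — an EMMA-style approximation useful when the panel
is structured.

`lit_scan` is a variance-heterogeneity (vQTL) scan standing in for
kernel-based latent-interaction software: unmodelled interactions that
involve a marker make the residual variance differ between its genotype
classes. Per marker, the additive effect is removed by OLS and the
squared residuals are compared across the genotype classes present with
a one-way ANOVA F-test (2 numerator df when all three classes occur).
The test is exactly invariant to the tested marker's own additive
effect, is calibrated under the null at the sample sizes used here
(checked by Monte-Carlo), and has high power against product-form
epistasis (checked by simulation). Externally computed p-value tables —
e.g. from dedicated GWAS/LIT software — can be imported instead via
`import_priors`; exact zeros are rejected rather than silently clipped.

No multiple-testing correction is applied: the embedding consumes raw
p-values and feature selection only uses ranks, so monotone transforms
are irrelevant.

**Leakage discipline.** Because both scans are functions of the
phenotype, cross-validation recomputes them inside every fold from the
training samples only. Each prior table records the exact sample
indices it saw; the CV driver asserts that this provenance is disjoint
from the test fold and fails hard otherwise.

## Network architecture

* **Local encoder** — a 1-D residual convolution stack over the marker
  axis (stem convolution, then residual blocks with strided
  convolutions and 1×1-conv skip paths) compresses the panel to a short
  token sequence; multi-head self-attention with a residual connection
  and layer normalization mixes information between tokens.
* **Global decoder** — the raw signed genotype row is compressed by a
  two-layer linear map with LeakyReLU into a small number of global
  tokens. These tokens form the attention **queries**; keys and values
  come from the local-encoder tokens. The cross-attention output is
  added back to the global tokens (residual) and flattened. The Q/K/V
  assignment is a design choice: the residual path must carry the
  global representation, so the global side queries the local side.
* **Omics fusion** (optional) — a second omics layer (e.g. metabolite
  intensities) is compressed by its own two-layer map to the fused
  width and combined as `out_omics + sigmoid(max(out_snp, out_omics))`
  elementwise; the increment over the omics path is always in (0, 1).
* **Head** — a three-layer MLP with LeakyReLU and dropout.

LeakyReLU is used in divisor form — x for x ≥ 0, x/a otherwise — with
a = 100 by default, i.e. negative slope 0.01.

Training minimizes MSE plus an explicit L2 penalty λ‖θ‖² with Adam
(penalty in the loss, so its gradient 2λθ flows through the optimizer's
moment estimates). Phenotypes are z-scored on the training fold and
destandardized at prediction. One configuration seed drives parameter
initialization, batch shuffling and dropout, so a fit is bit-for-bit
reproducible on the same data.

The network runs on a small in-package reverse-mode autodiff engine
(`iadep.nn.autograd`) written on numpy: broadcast-aware elementwise
ops, batched matmul, im2col-based 1-D convolution, softmax, layer
normalization, dropout. Its gradients are verified against finite
differences in the test suite.

### Numerical choices

* **Input channel scaling** — the −log₁₀ p channels can span [0, 300]
  while the dominance channel is binary; each channel is divided by its
  training-fold standard deviation inside the model's preprocessing
  state (the embedding values themselves are untouched). Without this
  the loss surface is badly conditioned.
* **Default hyperparameters** are sized for desk-scale panels
  (hundreds of samples, hundreds to a few thousand markers): stem
  kernel 7 stride 4, residual blocks with kernels (7, 3) and strides
  (4, 2), width 16, 4 attention heads, 2 global tokens, MLP (32, 16),
  dropout 0.1, lr 3e−3, λ = 1e−4, 60 epochs, batch 128. On such panels
  a leaner network both trains faster and generalizes better than a
  wide one; for larger panels the stride schedule and widths should be
  scaled with the marker count.
* **No early stopping** by default; the loss trace is recorded and a
  non-finite loss aborts with diagnostics instead of propagating NaNs.
* **Softmax** is computed with a detached per-row max shift (exactly
  gradient-neutral); ties in the fusion `max` route the gradient to the
  SNP branch.

## Classical baselines

* **GRM / GBLUP** — VanRaden's first method: G = ZZ′ / (2Σ pⱼ(1−pⱼ))
  with Z the dosage matrix centered by 2pⱼ (centered, not
  variance-scaled: the scaling constant printed above is exactly
  VanRaden's). Allele frequencies are taken from the full panel
  (training plus prediction samples), matching GBLUP's transductive
  character. Predictions use the standard mixed-model solution on the
  train/test blocks of G with a GLS intercept; variance components are
  REML-estimated on the training fold (per fold, not once per
  dataset). GBLUP equals marker-ridge BLUP with λ = σ²ₑ/σ²ᵤ; the test
  suite verifies this identity against an independent implementation.
* **Ridge regression** — closed-form solve of (X′X + λI)β = X′y on
  centered data; λ = 0 with rank-deficient X falls back to the
  minimum-norm solution and is flagged. In cross-validation λ defaults
  to an SVD-based GCV choice over a log grid.
* **REML heritability** — single-component GREML: after one
  eigendecomposition of G the restricted likelihood is a 1-D function
  of h² = σ²_g/(σ²_g+σ²ₑ), maximized by a grid pass plus bounded
  refinement. Exact (no Monte-Carlo), errors on non-convergence, and
  requires n ≥ 20.

## Synthetic data

The simulator exists so that every component is testable without
external downloads; it emulates the study conditions, not any
particular crop panel.

* **Genotypes** — two haplotypes per sample; per-marker allele
  frequency uniform in a configurable MAF range (default 0.05–0.5).
  LD is copy-with-mutation within blocks: each haplotype allele copies
  its left neighbour and re-draws with probability μ (default 0.1),
  giving tunable adjacent-marker r²; blocks are independent. This is
  deliberately not coalescent-accurate and carries no population
  structure or kinship confounding.
* **Traits** — A = Σ effect·signed dosage over additive QTL, D = Σ
  effect·heterozygote indicator, I = Σ effect·(signedᵢ×signedⱼ) over
  marker pairs, effects standard normal. Noise variance is set from the
  realized var(G) so that var(G)/var(y) equals the target heritability
  in expectation; the realized ratio is recorded for exact downstream
  checks. A + D + I = G holds exactly per sample.
* **Omics** — a configurable fraction of features are affine in G plus
  Gaussian noise; the rest are pure noise. This mimics an intermediate
  molecular layer without any feature correlation structure.

Because the simulated panels are unstructured and the architecture of
simulated traits is known, passing benchmarks here demonstrates correct
mechanics and the expected qualitative behaviour (calibration,
parameter recovery, the value of the embedding, the transductive/
inductive contrast) — not field performance on real breeding panels
with LD structure, relatedness and genotype-environment interaction.

## Evaluation

`make_folds(n, k, seed)` gives a deterministic partition with fold
sizes differing by ≤ 1 (k = n is leave-one-out). Two accuracy
summaries per run: scheme 1 (per-fold Pearson correlation; mean and
standard error sd/√k over folds — the SD is reported alongside since
either convention appears in the literature) and scheme 2 (one pooled
correlation over the out-of-fold predictions of all samples). A
constant prediction vector raises an undefined-correlation error, never
a silent 0.

`select_features` takes the union of the top p % markers by GWAS p and
by LIT p (ranks ascending, ties broken by marker order, so selections
are deterministic and monotone in p). `run_ablation` cross-validates
the three encodings on one shared fold plan so differences are
attributable to the encoding. `compare_cv_granularity` contrasts pooled
accuracy at two fold counts: a transductive method (GBLUP sees every
genotype through the GRM) should barely move, while an inductive
learner gains from the larger training fraction at high k.

## Problem sizes used in the shipped benchmarks

The acceptance script and heavy tests use desk-scale sizes chosen as
this package's standard benchmark conditions: calibration at n = 500
samples × 1000 markers over 10 seeds; heritability recovery at
n = 500 × 1000 over 20 seeds with a 5-point monotonicity grid;
end-to-end learning at n = 600 × 800, h² = 0.8, 5 seeds; the encoding
ablation at n = 360 × 300 with 10 large additive QTL, h² = 0.7,
3-fold, 2 seeds; and the 5-fold-vs-100-fold granularity contrast at
n = 300 × 250 with a reduced network. These sizes keep each experiment
in the minutes range on a single CPU while leaving the Monte-Carlo
margins comfortably wider than the assertion bands.

## Known limitations

* The latent-interaction channel is a marginal vQTL test, not a kernel
  test; interactions that produce no genotype-class variance
  heterogeneity (e.g. perfectly balanced sign-flipping pairs under
  symmetric allele frequencies) are invisible to it.
* The simulator's LD model is first-order Markov within blocks; it
  cannot produce long-range LD or population structure, so the mixed
  GWAS mode is exercised only for calibration, not for confounding
  correction.
* GBLUP assumes a homogeneous genetic architecture; the REML estimator
  is single-component (no dominance/epistasis GRMs).
* The autodiff engine is single-threaded numpy; panels beyond a few
  thousand markers call for smaller strides/widths and patience, and
  GPU-scale experiments are out of scope.
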