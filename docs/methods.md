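# Methods

## Model overview

`scldm` models log-normalized, centered single-cell expression x ∈ R^G in
two decoupled stages.

**Stage 1 — Gaussian VAE.** Encoder q_φ(z|x) = N(μ_φ(x), diag σ²_φ(x)) and
decoder p_θ(x|z) = N(f_θ(z), I) are symmetric ReLU MLPs (default widths
256–128, latent dimension d = 32). Training minimises the negative ELBO
with unit KL weight. The unit-variance Gaussian likelihood (squared-error
reconstruction) is the natural choice once expression has been
log-normalized and centered; count likelihoods (NB/ZINB) are deliberately
out of scope. After fitting, the posterior means of the training set are
standardised per dimension to mean 0, variance 1 and the statistics are
frozen ("latent batch normalisation"). This makes `encode` deterministic
and exactly invertible, and gives the second stage inputs on the scale its
Gaussian prior assumes.

**Stage 2 — latent DDPM.** The forward chain adds Gaussian noise in T
steps with per-step variances β_1..β_T; the closed-form marginal is
q(z_t|z_0) = N(√ᾱ_t z_0, (1−ᾱ_t) I) with ᾱ_t = Π_{s≤t}(1−β_s). A noise
prediction network ε_θ(z_t, t) — an MLP on [z_t, sinusoidal(t)], default
widths 128–128, time embedding 32 — is trained on the simplified
ε-matching objective with t uniform on {1..T} and fresh ε per example per
step. Reverse/ancestral sampling uses the DDPM update with σ_t² = β_t and
σ_1 = 0; the reverse-kernel variance is fixed, not learned. An exponential
moving average of the weights (decay 0.999, updated every optimizer step,
initialised at the initial weights) is used for all inference by default.

Training is strictly two-stage; the package offers no end-to-end mode. A
gene-list fingerprint stored in every checkpoint prevents pairing a
diffusion model with data whose preprocessing differs from what the VAE
saw.

All networks, gradients and the Adam optimizer are implemented directly on
numpy (`scldm/_nn.py`): the models are small latent-space MLPs for which
explicit reverse-mode code is simple, fast on one CPU, and makes the whole
pipeline bit-reproducible under a seed with no framework dependency.

## Noise schedules

Three β schedules are provided over [β_min, β_max] = [1e-5, 0.5e-2] by
default: linear (equally spaced), quadratic (equally spaced in √β, then
squared) and sigmoid (logistic ramp over [−6, 6], rescaled exactly onto
the bounds so β stays within them). The default range is calibrated for
T = 1000, where Σβ ≈ 2.5 and ᾱ_T ≈ 0.08. **When T is scaled down, β_max
should be scaled up to preserve Σβ** — the test and acceptance harnesses
use T = 200 with β_max = 0.025 for exactly this reason. The terminal
closed-form diagnostic `terminal_kl` reports KL(q(z_T|z_0) ‖ N(0, I)) both
in total nats and in nats per dimension; the per-dimension value is the
scale-free measure of chain convergence (the total grows linearly with d
for any fixed schedule) and is the quantity the package's convergence
checks bound. For the default schedule it is ≈ 0.004 nats/dim at d = 16.

## Interpolation

Two procedures generate a path between states x_1, x_2 on an equidistant
λ grid (default 2000 points, always including λ = 0 and 1):

* **prior-space**: encode, push both latents to step `t_mix` with one
  shared forward draw, mix linearly q̂(λ) = (1−λ)q̂_1 + λq̂_2, run the
  reverse process from `t_mix` down to 1, decode. The reverse start step
  equals `t_mix` (noise was only injected that far). `t_mix` controls
  granularity: small values preserve fine detail, values near T give
  coarser, more seed-varied paths; `t_mix = 0` reduces to plain VAE-latent
  interpolation.
* **latent-space**: mix in VAE latent space first, then noise to `t_noise`
  and denoise — cheaper, used when control over granularity is not needed.

Stochasticity is fixed: the endpoint forward draw and one J per reverse
step are drawn once and reused for every λ, so λ = 0/1 reproduce
single-endpoint generation exactly and paths are smooth in λ. Cell-state
endpoints are mean preprocessed expression per state (single cells also
work). Monotonicity of the similarity profile (Pearson r of each decoded
step against the two endpoint means) is assessed counting only violations
larger than 0.1% of the profile's total range, with a 5% violation budget
— smaller wiggles are numerical, not structural.

## Perturbation arithmetic

The response direction is the difference of group means, stimulated minus
control, over all non-held-out cells — optionally balanced per cell type —
computed at diffusion step `t_delta` (default T/10) after a shared-noise
forward push; `t_delta = 0` is the pure-VAE ablation. Prediction pushes
each held-out control cell to `t_delta` with shared noise, adds the delta,
denoises and decodes. Evaluation reports Pearson r between per-gene means
(overall and per cell type) plus per-gene distribution quantiles, because
a mean-matched but distribution-wrong prediction scores r = 1 on means
alone.

## Gene velocities

Velocities are first differences of decoded expression along the path
divided by Δλ (per-unit-λ units make them independent of path resolution),
optionally smoothed by a centred moving average. Fast-responder ranking
takes the top k = 10 genes by |velocity| per step over the first 40 steps
(400 entries before deduplication); signed ranking is available behind a
flag. Marker-by-difference ranks genes by |expr(t_b) − expr(t_a)| with
name-based tie-breaks. Ranked lists export as two-column `.rnk` files for
external enrichment tools; enrichment statistics themselves are out of
scope.

## Preprocessing

Library-size normalization to the median total count, log1p, selection of
the top n (default 2000) genes by normalized dispersion, then per-gene
centering — in that order, centering last so the VAE sees zero-mean
features. Dispersion is var/mean of the de-logged normalized counts,
z-scored within quantile bins of the mean (computed explicitly so the
selection is a pure function of the matrix at any gene count), with ties
broken lexicographically by gene name. Cells with zero total counts are a
hard error rather than a silent drop. Whether centering precedes or
follows HVG selection is configurable; the default is HVG first.

## Synthetic data

The generator emulates three dataset archetypes with full ground truth:
discrete clusters (Gaussian programmes in an 8-dim factor space mapped to
genes through a fixed random loading), a differentiation trajectory (per
gene response curves in λ: linear for most genes, steep logistic switches
for 20 designated master genes with midpoints in λ ∈ [0.02, 0.18]), and
paired control/stimulated conditions (a shared additive log-scale response
on 15% of genes — drawn from the expressed fraction so the shift is
identifiable after count sampling — with per-cell-type modulation).
Counts are Poisson draws from exponentiated log-rates with log-normal cell
size factors and independent Bernoulli dropout. Defaults mirror a small
real dataset (1390 cells × 1845 genes).

What it does *not* emulate: batch effects, ambient RNA, doublets,
gene–gene regulatory correlations beyond the factor structure, or
empirically calibrated overdispersion. Passing benchmarks on these
fixtures therefore demonstrates correctness of the machinery and
recoverability of programmed signal — not performance on real tissue.

## Problem sizes and harness conditions

Trained-model checks run at desk scale, chosen as the package's standard
benchmark conditions: the two-cluster training-sanity run uses the full
1390 × 1845 fixture (d = 16, T = 200); prior-quality TVD comparisons use
600 × 300 fixtures over three seeds; the interpolation harness uses an
800 × 300 trajectory with strengthened endpoint programmes and moderate
noise (σ = 0.15, dropout 0.1, well-expressed genes) — interpolation between
states presumes the states are well measured and distinct; the
perturbation harness uses 1200 × 300 with a strong response
(`response_scale = 2`) and a well-trained higher-capacity VAE (d = 16,
widths 256–128, 300 epochs), since latent vector arithmetic relies on the
encoder being close to additive, which an under-trained encoder is not.
Latent-shift recovery is validated on the uniform-response variant
(modulation off) against the held-out type's own latent shift — the
reference the estimator never saw — within sampling error; cell-type
modulation is a real systematic deviation and is exercised by the
prediction benchmark instead.

## Numerical choices and degenerate inputs

* Posterior log-variances are clipped to ±10 to avoid overflow early in
  training; non-finite losses abort with the epoch/step index.
* Latent standardisation refuses zero-variance dimensions (naming them)
  and data sets with fewer than 2 cells fall back to the identity
  transform.
* Histogram TVD uses 50 equal-width bins spanning the pooled range per
  dimension, averaged over dimensions; it is symmetric, invariant to
  common affine transforms, and 0 for identical samples by construction.
  A dimension whose pooled values are all equal contributes 0.
* Random-number discipline: every stochastic concern (weight init,
  training batches, generation, interpolation noise, perturbation noise)
  draws from its own named `SeedSequence` stream, so fixing one seed fixes
  one behaviour without coupling others.
* T = 1 schedules are the single value β_min; equal β bounds give a
  constant schedule for every kind.

## Known limitations

Gaussian reconstruction ignores count overdispersion; the latent
arithmetic assumes approximate additivity of the encoder, which degrades
for under-trained or low-capacity models; DDIM/ODE samplers, classifier
guidance and gamma-noise diffusion are not implemented; UMAP rendering and
enrichment analysis are delegated to external tools.
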