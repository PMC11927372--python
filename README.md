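# scldm — latent diffusion models for single-cell transcriptomics

`scldm` is a two-stage generative model for scRNA-seq expression data. A
Gaussian variational autoencoder (VAE) first learns a low-dimensional
embedding of log-normalized expression; a denoising diffusion probabilistic
model (DDPM) then learns the distribution of those latents. Sampling the
diffusion prior and decoding gives realistic novel cells without the
"prior hole" problem of plain VAEs, and the learned latent geometry
supports three downstream analyses:

* **cell-state interpolation** between two states at controllable
  granularity (the diffusion mixing step `t_mix` sets coarse vs fine),
* **perturbation-response prediction** for held-out cell types by vector
  arithmetic in the diffusion latent space, and
* **gene-velocity ranking** of fast-responder (master-regulator candidate)
  genes along an interpolation path.

## Model

The VAE maximises the evidence lower bound with a standard-normal prior
and unit-variance Gaussian likelihood:

    L(θ, φ; x) = −KL(q_φ(z|x) ‖ N(0, I)) + E_{q_φ(z|x)}[log p_θ(x|z)]

Encoded posterior means are standardised per dimension (frozen statistics)
before the second stage. The diffusion model uses the forward chain
q(z_t|z_{t−1}) = N(√(1−β_t) z_{t−1}, β_t I) with closed-form marginal
q(z_t|z_0) = N(√ᾱ_t z_0, (1−ᾱ_t) I), ᾱ_t = Π_{s≤t}(1−β_s), and trains a
noise-prediction MLP ε_θ(z_t, t) on

    L = E_{t, z_0, ε} ‖ ε − ε_θ(√ᾱ_t z_0 + √(1−ᾱ_t) ε, t) ‖².

Ancestral sampling applies
z_{t−1} = (1/√α_t)(z_t − (1−α_t)/√(1−ᾱ_t) ε_θ(z_t, t)) + σ_t J with
σ_t² = β_t, σ_1 = 0. β schedules are linear, quadratic or sigmoid over
[1e-5, 0.5e-2]; an exponential moving average (decay 0.999) of the network
weights is used at inference. Training and inference run on plain numpy —
the networks are small latent-space MLPs with hand-written gradients, so
no GPU or deep-learning framework is needed.

## Worked example

```python
import numpy as np
import scldm as m

# synthetic two-cluster dataset with known ground truth
adata, truth = m.generate_dataset(
    m.GeneratorSpec(n_cells=600, n_genes=300, archetype="clusters", seed=10))
pp = m.preprocess(adata, m.PreprocessConfig(n_hvg=200))

vae = m.GaussianVAE(pp, latent_dim=8, hidden=(128, 64), seed=0).fit(epochs=60)
print(vae.summary())

sched = m.build_schedule("linear", T=200, beta_min=1e-5, beta_max=0.025)
ddm = m.LatentDiffusion(vae.encode(pp), sched, seed=0).fit(epochs=500)

res = m.compare_priors(vae, ddm, pp, n_samples=2000, seed=0)
print(f"TVD(real, DDM)      = {res['tvd_ddm']:.3f}")
print(f"TVD(real, VAE prior) = {res['tvd_vae_prior']:.3f}")
```

which prints

```
Gaussian VAE results
  cells x genes : 600 x 200
  latent dim    : 8
  hidden layers : (128, 64)
  epochs        : 60
  seed          : 0
  loss (first -> last): 623.0970 -> 66.6658
TVD(real, DDM)      = 0.119
TVD(real, VAE prior) = 0.192
```

The total variation distance (TVD, 0 = indistinguishable, 1 = disjoint)
between the real latent embedding and generated samples is clearly smaller
for the diffusion prior than for N(0, I) draws: the embedding of two
cell clusters is bimodal, the VAE prior is not, and the DDM learns the
difference. `m.interpolate_qspace`, `m.estimate_delta` /
`m.predict_perturbed` and `m.gene_velocity` / `m.rank_fast_responders`
continue from these two fitted objects; the `scldm` command line exposes
the same stages (`scldm make-fixture`, `preprocess`, `train-vae`,
`train-ddm`, `generate`, `interpolate`, `perturb`, `velocity`,
`eval-prior`).

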