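"""Shared fixtures: synthetic datasets and session-scoped trained models.

Model training is expensive relative to everything else, so each trained
two-stage model is fitted once per session at a documented desk scale and
shared by all tests that inspect it.
"""

from __future__ import annotations

import numpy as np
import pytest

import scldm as m

# fixture-level study conditions (see docs/methods.md): the interpolation /
# perturbation harnesses emulate well-measured, strongly distinct states
CLEAN_NOISE = dict(sigma=0.15, dropout=0.1, base_logmean_range=(0.5, 3.0),
                   libsize_sd=0.2)


def small_schedule(T: int = 200) -> m.NoiseSchedule:
    # beta_max scaled so the total injected noise matches the default
    # T=1000 schedule (sum of betas ~ 2.5, terminal alpha-bar ~ 0.08)
    return m.build_schedule("linear", T, 1e-5, 0.025)


def two_stage(adata, *, latent_dim=8, hidden=(128, 64), vae_epochs=60,
              ddm_hidden=(128, 128), ddm_epochs=500, n_hvg=200, seed=0):
    pp = m.preprocess(adata, m.PreprocessConfig(n_hvg=n_hvg))
    vae = m.GaussianVAE(pp, latent_dim=latent_dim, hidden=hidden,
                        seed=seed).fit(epochs=vae_epochs)
    Z = vae.encode(pp)
    ddm = m.LatentDiffusion(Z, small_schedule(), hidden=ddm_hidden,
                            seed=seed).fit(epochs=ddm_epochs)
    return pp, vae, ddm


@pytest.fixture(scope="session")
def cluster_models():
    """Two well-separated clusters (bimodal latent), trained both stages."""
    spec = m.GeneratorSpec(n_cells=600, n_genes=300, archetype="clusters", seed=10)
    adata, truth = m.generate_dataset(spec)
    pp, vae, ddm = two_stage(adata, seed=0)
    return {"adata": adata, "pp": pp, "vae": vae, "ddm": ddm, "truth": truth}


@pytest.fixture(scope="session")
def full_scale_models():
    """Two-cluster fixture at the full study scale (1390 x 1845, d=16, T=200)."""
    spec = m.GeneratorSpec(seed=0)  # defaults: 1390 cells x 1845 genes
    adata, _ = m.generate_dataset(spec)
    pp = m.preprocess(adata, m.PreprocessConfig(n_hvg=1845, normalize=True))
    vae = m.GaussianVAE(pp, latent_dim=16, hidden=(256, 128), seed=0).fit(epochs=30)
    Z = vae.encode(pp)
    ddm = m.LatentDiffusion(Z, small_schedule(), hidden=(128, 128), seed=0).fit(epochs=300)
    return {"pp": pp, "vae": vae, "ddm": ddm}


@pytest.fixture(scope="session")
def trajectory_models():
    """Differentiation-axis fixture with designated master genes."""
    spec = m.GeneratorSpec(n_cells=800, n_genes=300, archetype="trajectory",
                           seed=3, traj_program_sd=1.2, **CLEAN_NOISE)
    adata, truth = m.generate_dataset(spec)
    pp, vae, ddm = two_stage(adata, vae_epochs=120, n_hvg=300, seed=0)
    X = np.asarray(pp.X)
    lam = pp.obs["lambda_true"].to_numpy()
    xa, xb = X[lam < 0.1].mean(0), X[lam > 0.9].mean(0)
    return {"adata": adata, "pp": pp, "vae": vae, "ddm": ddm, "truth": truth,
            "xa": xa, "xb": xb, "Z": vae.encode(pp)}


def _perturbation_models(modulation_sd: float):
    spec = m.GeneratorSpec(n_cells=1200, n_genes=300, archetype="perturbation",
                           seed=4, response_scale=2.0, center_scale=1.0,
                           modulation_sd=modulation_sd, **CLEAN_NOISE)
    adata, truth = m.generate_dataset(spec)
    pp, vae, ddm = two_stage(adata, latent_dim=16, hidden=(256, 128),
                             vae_epochs=300, ddm_epochs=400, n_hvg=300, seed=0)
    return {"adata": adata, "pp": pp, "vae": vae, "ddm": ddm, "truth": truth,
            "Z": vae.encode(pp)}


@pytest.fixture(scope="session")
def perturbation_models():
    """Control/stimulated fixture with cell-type-specific modulation."""
    return _perturbation_models(0.2)


@pytest.fixture(scope="session")
def uniform_shift_models():
    """Control/stimulated fixture with the same additive shift for all types."""
    return _perturbation_models(0.0)


@pytest.fixture(scope="session")
def gauss1d_ddm():
    """Diffusion model trained on 1-d standard-normal latents (Bayes-floor toy)."""
    rng = np.random.default_rng(0)
    Z = rng.standard_normal((5000, 1))
    sched = m.build_schedule("linear", 50, 1e-4, 0.05)
    ddm = m.LatentDiffusion(Z, sched, hidden=(64, 64), seed=0).fit(epochs=80)
    return {"Z": Z, "sched": sched, "ddm": ddm}


@pytest.fixture()
def truth_path(trajectory_models):
    """Noiseless generator trajectory wrapped as an interpolation path."""
    truth = trajectory_models["truth"]
    lam = np.linspace(0.0, 1.0, 200)
    expr = truth.trajectory_log_expression(lam)
    return m.InterpolationPath(lambdas=lam, t_mix=0, method="qspace",
                               latents=np.zeros((len(lam), 1)),
                               expressions=expr, gene_names=truth.gene_names)
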