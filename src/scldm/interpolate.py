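"""Latent-space interpolation between two cell states.

Two procedures, both with fixed stochasticity (every random draw is made
once and reused for all λ so the path varies only through λ):

prior-space (``interpolate_qspace``)
    Encode both endpoints, push each to diffusion step ``t_mix`` with the
    closed-form forward process, interpolate linearly on an equidistant λ
    grid in that prior space, then run the reverse process t_mix → 1 and
    decode. ``t_mix`` sets the granularity: small values keep fine detail,
    values near T give coarser, more varied paths. ``t_mix = 0`` degenerates
    to plain VAE-latent interpolation.

latent-space (``interpolate_zspace``)
    Interpolate in the VAE latent first, then add forward noise at
    ``t_noise`` and denoise back — cheaper, less controllable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

from .diffusion import DiffusionResults, q_sample
from .vae import VAEResults


@dataclass
class InterpolationPath:
    """A λ grid with its per-step latents and decoded expressions."""

    lambdas: np.ndarray
    t_mix: int
    method: str                      # "qspace" | "zspace"
    latents: np.ndarray              # per-λ normalised VAE-space vectors
    expressions: np.ndarray          # per-λ decoded gene vectors
    endpoint_descriptors: dict = field(default_factory=dict)
    gene_names: list | None = None
    seed: int | None = None

    @property
    def n_steps(self) -> int:
        return len(self.lambdas)

    def to_anndata(self) -> ad.AnnData:
        var_index = (pd.Index(self.gene_names, name="gene") if self.gene_names
                     else pd.Index([f"g{i}" for i in range(self.expressions.shape[1])]))
        adata = ad.AnnData(
            X=self.expressions,
            obs=pd.DataFrame({"lambda": self.lambdas, "t_mix": self.t_mix},
                             index=[f"step_{i:05d}" for i in range(self.n_steps)]),
            var=pd.DataFrame(index=var_index),
        )
        adata.obsm["latent"] = self.latents
        adata.uns["interpolation"] = {"method": self.method, "t_mix": self.t_mix,
                                      "seed": self.seed, **self.endpoint_descriptors}
        return adata


def _lambda_grid(n_steps: int) -> np.ndarray:
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2 (need both endpoints)")
    return np.linspace(0.0, 1.0, n_steps)


def _prep_endpoint(vae: VAEResults, x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 2:  # a set of cells: use the mean state
        x = x.mean(axis=0)
    return vae.encode(x[None, :])


def interpolate_qspace(vae: VAEResults, ddm: DiffusionResults, x1, x2,
                       t_mix: int, n_steps: int = 2000, seed: int = 0,
                       use_ema: bool = True) -> InterpolationPath:
    """Interpolate in the diffusion prior space at step ``t_mix``."""
    lam = _lambda_grid(n_steps)
    z1, z2 = _prep_endpoint(vae, x1), _prep_endpoint(vae, x2)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 101)))
    if t_mix == 0:
        z_path = (1.0 - lam)[:, None] * z1 + lam[:, None] * z2
    else:
        sched = ddm.schedule
        sched._check_t(t_mix)
        eps = rng.standard_normal(z1.shape)        # one draw, shared by both ends
        q1 = q_sample(z1, t_mix, eps, sched)
        q2 = q_sample(z2, t_mix, eps, sched)
        q_path = (1.0 - lam)[:, None] * q1 + lam[:, None] * q2
        noise_record = ddm.make_noise_record(t_mix, rng)
        z_path = ddm.denoise_from(q_path, t_mix, noise_record=noise_record,
                                  use_ema=use_ema)
    expr = vae.decode(z_path)
    return InterpolationPath(
        lambdas=lam, t_mix=int(t_mix), method="qspace", latents=z_path,
        expressions=expr, gene_names=vae.gene_names, seed=seed,
        endpoint_descriptors={"endpoint_kind": "mean-or-cell"},
    )


def interpolate_zspace(vae: VAEResults, ddm: DiffusionResults, x1, x2,
                       t_noise: int, n_steps: int = 2000, seed: int = 0,
                       use_ema: bool = True) -> InterpolationPath:
    """Interpolate in VAE latent space, then noise-and-denoise at ``t_noise``."""
    lam = _lambda_grid(n_steps)
    z1, z2 = _prep_endpoint(vae, x1), _prep_endpoint(vae, x2)
    z_path = (1.0 - lam)[:, None] * z1 + lam[:, None] * z2
    rng = np.random.default_rng(np.random.SeedSequence((seed, 102)))
    if t_noise > 0:
        sched = ddm.schedule
        sched._check_t(t_noise)
        eps = rng.standard_normal((1, z_path.shape[1]))
        z_noisy = q_sample(z_path, t_noise, np.broadcast_to(eps, z_path.shape), sched)
        noise_record = ddm.make_noise_record(t_noise, rng)
        z_path = ddm.denoise_from(z_noisy, t_noise, noise_record=noise_record,
                                  use_ema=use_ema)
    expr = vae.decode(z_path)
    return InterpolationPath(
        lambdas=lam, t_mix=int(t_noise), method="zspace", latents=z_path,
        expressions=expr, gene_names=vae.gene_names, seed=seed,
        endpoint_descriptors={"endpoint_kind": "mean-or-cell"},
    )


def similarity_profile(path: InterpolationPath, ref_a: np.ndarray,
                       ref_b: np.ndarray) -> pd.DataFrame:
    """Pearson correlation of every decoded step against two reference means."""
    ref_a = np.asarray(ref_a, dtype=float).ravel()
    ref_b = np.asarray(ref_b, dtype=float).ravel()
    out = np.empty((path.n_steps, 2))
    for j, ref in enumerate((ref_a, ref_b)):
        if ref.std() == 0:
            raise ValueError(f"reference {'ab'[j]} has zero variance")
    for i, row in enumerate(path.expressions):
        if row.std() == 0:
            raise ValueError(f"decoded step {i} has zero variance; "
                             "correlation undefined")
        out[i, 0] = np.corrcoef(row, ref_a)[0, 1]
        out[i, 1] = np.corrcoef(row, ref_b)[0, 1]
    return pd.DataFrame({"lambda": path.lambdas, "corr_a": out[:, 0],
                         "corr_b": out[:, 1]})


def support_distances(path: InterpolationPath, real_latents: np.ndarray) -> dict:
    """Nearest-neighbour test that the path stays on the data manifold.

    Returns each path point's distance to the closest real encoded cell,
    together with the 99th percentile of real-data nearest-neighbour
    distances (the acceptance threshold: no path point should sit farther
    from the data cloud than real cells sit from each other).
    """
    from scipy.spatial import cKDTree

    real = np.asarray(real_latents, dtype=float)
    tree = cKDTree(real)
    path_d, _ = tree.query(path.latents, k=1)
    real_nn, _ = tree.query(real, k=2)
    real_d = real_nn[:, 1]
    return {
        "path_distances": path_d,
        "real_nn_q99": float(np.quantile(real_d, 0.99)),
        "frac_within": float(np.mean(path_d <= np.quantile(real_d, 0.99))),
    }


def plot_similarity(profile: pd.DataFrame, ax=None):
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(profile["lambda"], profile["corr_a"], label="endpoint A")
    ax.plot(profile["lambda"], profile["corr_b"], label="endpoint B")
    ax.set_xlabel("lambda"); ax.set_ylabel("Pearson r"); ax.legend()
    return ax
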