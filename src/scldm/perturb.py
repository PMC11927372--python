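"""Perturbation-response prediction by latent vector arithmetic.

The response direction is estimated scGen-style as the difference of group
means — stimulated minus control — but taken in the diffusion latent space
at a configurable step ``t_delta`` (0 = plain VAE space, the ablation
case; default T/10). The held-out cell type's stimulated cells never enter
the estimate. Prediction pushes each held-out control cell to ``t_delta``
with shared forward noise, adds the delta, denoises back and decodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

from .diffusion import DiffusionResults, q_sample
from .vae import VAEResults


@dataclass
class PerturbationDelta:
    """Estimated latent response vector and its provenance."""

    vector: np.ndarray
    t_delta: int
    source_celltypes: list = field(default_factory=list)
    holdout: str | None = None
    n_control: int = 0
    n_stimulated: int = 0


def _latents_at(vae: VAEResults, ddm: DiffusionResults, X, t_delta: int,
                rng: np.random.Generator) -> np.ndarray:
    """Encode cells and (optionally) diffuse them to ``t_delta``."""
    z = vae.encode(X)
    if t_delta == 0:
        return z
    eps = rng.standard_normal(z.shape)
    return q_sample(z, t_delta, eps, ddm.schedule)


def estimate_delta(vae: VAEResults, ddm: DiffusionResults, adata: ad.AnnData,
                   holdout_celltype: str | None, t_delta: int | None = None,
                   seed: int = 0, condition_key: str = "condition",
                   celltype_key: str = "cell_type",
                   control_label: str = "control",
                   stimulated_label: str = "stimulated",
                   balanced: bool = False) -> PerturbationDelta:
    """Stimulated-minus-control mean difference at diffusion step ``t_delta``.

    ``balanced=True`` averages per-cell-type means instead of pooling cells,
    protecting the delta from cell-type composition imbalance.
    """
    if t_delta is None:
        t_delta = ddm.schedule.T // 10
    obs = adata.obs
    keep = np.ones(adata.n_obs, dtype=bool)
    if holdout_celltype is not None:
        keep &= (obs[celltype_key].astype(str) != str(holdout_celltype)).to_numpy()
    cond = obs[condition_key].astype(str).to_numpy()
    ctrl_mask = keep & (cond == control_label)
    stim_mask = keep & (cond == stimulated_label)
    if ctrl_mask.sum() == 0 or stim_mask.sum() == 0:
        raise ValueError(
            f"insufficient data outside holdout {holdout_celltype!r}: "
            f"{int(ctrl_mask.sum())} control, {int(stim_mask.sum())} stimulated")

    rng = np.random.default_rng(np.random.SeedSequence((seed, 201)))
    lat = _latents_at(vae, ddm, adata, t_delta, rng)
    if balanced:
        types = obs[celltype_key].astype(str).to_numpy()
        used = sorted(set(types[keep]))
        stim_mean = np.mean([lat[stim_mask & (types == ty)].mean(axis=0)
                             for ty in used], axis=0)
        ctrl_mean = np.mean([lat[ctrl_mask & (types == ty)].mean(axis=0)
                             for ty in used], axis=0)
    else:
        stim_mean = lat[stim_mask].mean(axis=0)
        ctrl_mean = lat[ctrl_mask].mean(axis=0)
    return PerturbationDelta(
        vector=stim_mean - ctrl_mean, t_delta=int(t_delta),
        source_celltypes=sorted(set(obs[celltype_key].astype(str)[keep])),
        holdout=None if holdout_celltype is None else str(holdout_celltype),
        n_control=int(ctrl_mask.sum()), n_stimulated=int(stim_mask.sum()),
    )


def shift_latents(vae: VAEResults, ddm: DiffusionResults, X,
                  delta: np.ndarray, t_delta: int, seed: int = 0,
                  use_ema: bool = True) -> np.ndarray:
    """Latent pathway: encode → diffuse(t_delta) → +delta → denoise.

    With ``delta = 0`` this is the shared-noise identity pathway; returns
    normalised VAE-space latents.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 202)))
    z = vae.encode(X)
    if t_delta == 0:
        return z + delta
    eps = rng.standard_normal(z.shape)
    q = q_sample(z, t_delta, eps, ddm.schedule) + delta
    noise_record = ddm.make_noise_record(t_delta, rng)
    return ddm.denoise_from(q, t_delta, noise_record=noise_record, use_ema=use_ema)


def predict_perturbed(vae: VAEResults, ddm: DiffusionResults,
                      controls: ad.AnnData | np.ndarray, delta: PerturbationDelta,
                      seed: int = 0, use_ema: bool = True):
    """Predict one perturbed expression profile per input control cell."""
    z_shift = shift_latents(vae, ddm, controls, delta.vector, delta.t_delta,
                            seed=seed, use_ema=use_ema)
    expr = vae.decode(z_shift)
    if isinstance(controls, ad.AnnData):
        pred = ad.AnnData(X=expr, obs=controls.obs.copy(), var=controls.var.copy())
        pred.obs["predicted"] = True
        return pred
    return expr


def _mat(x) -> np.ndarray:
    if isinstance(x, ad.AnnData):
        from .io import _dense
        return _dense(x.X)
    return np.atleast_2d(np.asarray(x, dtype=float))


def evaluate_prediction(pred, real_stimulated, celltype_key: str = "cell_type",
                        genes: list | None = None) -> dict:
    """Score predictions against real stimulated cells.

    Returns Pearson r between per-gene means (overall and per cell type
    when labels are available on both inputs) plus per-gene distribution
    quantiles for an optional gene list — the mean correlation can be
    perfect while full distributions diverge, so both are reported.
    """
    P, R = _mat(pred), _mat(real_stimulated)
    if P.shape[0] == 0 or R.shape[0] == 0:
        raise ValueError("empty cell set")
    if P.shape[1] != R.shape[1]:
        raise ValueError(f"gene spaces differ: {P.shape[1]} vs {R.shape[1]}")

    rows = [("all", P.shape[0], R.shape[0],
             float(np.corrcoef(P.mean(axis=0), R.mean(axis=0))[0, 1]))]
    if (isinstance(pred, ad.AnnData) and isinstance(real_stimulated, ad.AnnData)
            and celltype_key in pred.obs and celltype_key in real_stimulated.obs):
        pt = pred.obs[celltype_key].astype(str).to_numpy()
        rt = real_stimulated.obs[celltype_key].astype(str).to_numpy()
        for ty in sorted(set(pt) & set(rt)):
            p, r = P[pt == ty], R[rt == ty]
            rows.append((ty, p.shape[0], r.shape[0],
                         float(np.corrcoef(p.mean(axis=0), r.mean(axis=0))[0, 1])))
    table = pd.DataFrame(rows, columns=["cell_type", "n_pred", "n_real", "pearson_r"])

    quantiles = None
    if genes is not None:
        qs = np.array([0.1, 0.25, 0.5, 0.75, 0.9])
        if isinstance(pred, ad.AnnData):
            idx = [list(pred.var_names).index(g) for g in genes]
        else:
            idx = list(genes)
        rec = []
        for g, j in zip(genes, idx):
            rec.append({"gene": g,
                        **{f"pred_q{int(q*100)}": float(np.quantile(P[:, j], q)) for q in qs},
                        **{f"real_q{int(q*100)}": float(np.quantile(R[:, j], q)) for q in qs}})
        quantiles = pd.DataFrame(rec)
    return {"correlations": table,
            "r_all": float(table.loc[table["cell_type"] == "all", "pearson_r"].iloc[0]),
            "gene_quantiles": quantiles}
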