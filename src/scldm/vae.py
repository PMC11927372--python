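"""First-stage Gaussian variational autoencoder on preprocessed expression.

The model maximises the evidence lower bound

    L(θ, φ; x) = −KL(q_φ(z|x) ‖ p(z)) + E_{q_φ(z|x)}[log p_θ(x|z)]

with a standard-normal prior p(z) = N(0, I) and a unit-variance Gaussian
reconstruction likelihood (mean-squared-error up to constants), which is
the natural choice for centered log-normalized expression. Encoder and
decoder are symmetric ReLU MLPs.

Training is full numpy with a hand-rolled reverse pass; everything is
deterministic under the seed. After fitting, the encoded posterior means
of the training set are standardised per dimension ("latent batch
normalisation") and the frozen statistics are stored so that ``encode`` is
deterministic and exactly invertible — the diffusion stage is trained on
these normalised coordinates.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd

from ._nn import Adam, Params, clone_params, init_mlp, mlp_backward, mlp_forward

_LOGVAR_CLIP = 10.0


class LatentNormalizer:
    """Frozen per-dimension affine standardisation of latent coordinates."""

    def __init__(self, mean: np.ndarray, std: np.ndarray):
        self.mean = np.asarray(mean, dtype=float)
        self.std = np.asarray(std, dtype=float)

    @classmethod
    def fit(cls, Z: np.ndarray) -> "LatentNormalizer":
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        if Z.shape[0] < 2:
            raise ValueError("latent normalization needs at least 2 cells")
        mean = Z.mean(axis=0)
        std = Z.std(axis=0)
        dead = np.flatnonzero(std < 1e-12)
        if dead.size:
            raise ValueError(f"zero-variance latent dimension(s): {dead.tolist()}")
        return cls(mean, std)

    @classmethod
    def identity(cls, d: int) -> "LatentNormalizer":
        return cls(np.zeros(d), np.ones(d))

    def transform(self, Z: np.ndarray) -> np.ndarray:
        return (np.asarray(Z, dtype=float) - self.mean) / self.std

    def inverse(self, Z: np.ndarray) -> np.ndarray:
        return np.asarray(Z, dtype=float) * self.std + self.mean


def normalize_latent(Z_raw: np.ndarray) -> tuple[np.ndarray, LatentNormalizer]:
    """Standardise raw latents to per-dimension mean 0, variance 1."""
    norm = LatentNormalizer.fit(Z_raw)
    return norm.transform(Z_raw), norm


def gene_fingerprint(gene_names) -> str:
    """Stable hash of the gene list, used for checkpoint provenance."""
    joined = "\n".join(str(g) for g in gene_names)
    return hashlib.sha256(joined.encode()).hexdigest()


def _as_matrix(data):
    if isinstance(data, ad.AnnData):
        from .io import _dense
        return _dense(data.X), list(data.var_names)
    X = np.atleast_2d(np.asarray(data, dtype=float))
    return X, None


class GaussianVAE:
    """Model object: holds the training matrix and the architecture.

    ``fit`` returns a :class:`VAEResults` carrying the trained parameters,
    the per-epoch loss trace and the frozen latent normalisation.
    """

    def __init__(self, data, latent_dim: int = 32, hidden: tuple = (256, 128),
                 kl_weight: float = 1.0, seed: int = 0):
        if latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        self.X, self.gene_names = _as_matrix(data)
        self.n_cells, self.n_genes = self.X.shape
        self.latent_dim = int(latent_dim)
        self.hidden = tuple(int(h) for h in hidden)
        self.kl_weight = float(kl_weight)
        self.seed = int(seed)

    @classmethod
    def from_anndata(cls, adata: ad.AnnData, **kwargs) -> "GaussianVAE":
        return cls(adata, **kwargs)

    # -- parameter bookkeeping ------------------------------------------------
    def _init_params(self, rng: np.random.Generator) -> Params:
        enc_sizes = [self.n_genes, *self.hidden, 2 * self.latent_dim]
        dec_sizes = [self.latent_dim, *reversed(self.hidden), self.n_genes]
        params = init_mlp(enc_sizes, rng, name="enc")
        params.update(init_mlp(dec_sizes, rng, name="dec"))
        return params

    def _posterior(self, params: Params, X: np.ndarray):
        out, cache = mlp_forward(params, X, name="enc")
        mu, logvar = out[:, :self.latent_dim], out[:, self.latent_dim:]
        return mu, np.clip(logvar, -_LOGVAR_CLIP, _LOGVAR_CLIP), cache

    def _loss_and_grads(self, params: Params, X: np.ndarray, eps: np.ndarray):
        n = X.shape[0]
        mu, logvar, enc_cache = self._posterior(params, X)
        std = np.exp(0.5 * logvar)
        z = mu + std * eps
        xhat, dec_cache = mlp_forward(params, z, name="dec")

        resid = xhat - X
        recon = 0.5 * np.sum(resid * resid, axis=1)
        kl = -0.5 * np.sum(1.0 + logvar - mu * mu - np.exp(logvar), axis=1)
        total = float(np.mean(recon + self.kl_weight * kl))

        g_xhat = resid / n
        dec_grads, g_z = mlp_backward(params, dec_cache, g_xhat, name="dec")
        g_mu = g_z + self.kl_weight * mu / n
        g_logvar = (g_z * 0.5 * std * eps
                    + self.kl_weight * 0.5 * (np.exp(logvar) - 1.0) / n)
        enc_grads, _ = mlp_backward(params, enc_cache,
                                    np.concatenate([g_mu, g_logvar], axis=1), name="enc")
        grads = {**enc_grads, **dec_grads}
        return total, float(np.mean(recon)), float(np.mean(kl)), grads

    # -- training -------------------------------------------------------------
    def fit(self, epochs: int = 100, batch_size: int = 128, lr: float = 1e-3) -> "VAEResults":
        """Train by Adam on minibatches; deterministic given the seed."""
        ss = np.random.SeedSequence(self.seed)
        init_rng, train_rng = [np.random.default_rng(s) for s in ss.spawn(2)]
        params = self._init_params(init_rng)
        opt = Adam(params, lr=lr)
        trace = []
        for epoch in range(epochs):
            order = train_rng.permutation(self.n_cells)
            tot = rec = kl = 0.0
            nb = 0
            for start in range(0, self.n_cells, batch_size):
                idx = order[start:start + batch_size]
                eps = train_rng.standard_normal((len(idx), self.latent_dim))
                t, r, k, grads = self._loss_and_grads(params, self.X[idx], eps)
                if not np.isfinite(t):
                    raise RuntimeError(f"non-finite VAE loss at epoch {epoch}")
                opt.step(params, grads)
                tot += t; rec += r; kl += k; nb += 1
            trace.append((epoch, tot / nb, rec / nb, kl / nb))
        history = pd.DataFrame(trace, columns=["epoch", "total", "recon", "kl"])
        return VAEResults(self, params, history)


class VAEResults:
    """Fitted VAE: encode/decode maps, loss trace, latent normalisation."""

    def __init__(self, model: GaussianVAE, params: Params, history: pd.DataFrame,
                 latent_norm: LatentNormalizer | None = None):
        self.model = model
        self.params = params
        self.history = history
        self.seed = model.seed
        self.latent_dim = model.latent_dim
        self.n_genes = model.n_genes
        self.gene_names = model.gene_names
        self.gene_hash = (gene_fingerprint(model.gene_names)
                          if model.gene_names is not None else None)
        if latent_norm is None:
            Z_raw = self.encode_raw(model.X)
            latent_norm = (LatentNormalizer.fit(Z_raw) if len(Z_raw) >= 2
                           else LatentNormalizer.identity(self.latent_dim))
        self.latent_norm = latent_norm

    # -- maps -----------------------------------------------------------------
    def _check_genes(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_genes:
            raise ValueError(f"expected {self.n_genes} genes, got {X.shape[1]}")
        return X

    def posterior(self, X) -> tuple[np.ndarray, np.ndarray]:
        """Per-cell posterior mean and log-variance (no sampling)."""
        X, _ = _as_matrix(X)
        X = self._check_genes(X)
        mu, logvar, _ = self.model._posterior(self.params, X)
        return mu, logvar

    def encode_raw(self, X) -> np.ndarray:
        return self.posterior(X)[0]

    def encode(self, X) -> np.ndarray:
        """Posterior means in normalised latent coordinates; deterministic."""
        return self.latent_norm.transform(self.encode_raw(X))

    def decode_raw(self, Z: np.ndarray) -> np.ndarray:
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        if Z.shape[1] != self.latent_dim:
            raise ValueError(f"expected latent width {self.latent_dim}, got {Z.shape[1]}")
        out, _ = mlp_forward(self.params, Z, name="dec")
        return out

    def decode(self, Z: np.ndarray) -> np.ndarray:
        """Map normalised latent coordinates back to gene space."""
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        if Z.shape[1] != self.latent_dim:
            raise ValueError(f"expected latent width {self.latent_dim}, got {Z.shape[1]}")
        return self.decode_raw(self.latent_norm.inverse(Z))

    def reconstruct(self, X) -> np.ndarray:
        return self.decode(self.encode(X))

    def elbo_terms(self, X, eps: np.ndarray | None = None) -> dict:
        """Loss components on a matrix; ``eps=None`` uses zero noise."""
        X, _ = _as_matrix(X)
        X = self._check_genes(X)
        if eps is None:
            eps = np.zeros((X.shape[0], self.latent_dim))
        total, recon, kl, _ = self.model._loss_and_grads(self.params, X, eps)
        return {"total": total, "recon": recon, "kl": kl}

    # -- reporting ------------------------------------------------------------
    def summary(self) -> str:
        h = self.history
        lines = [
            "Gaussian VAE results",
            f"  cells x genes : {self.model.n_cells} x {self.n_genes}",
            f"  latent dim    : {self.latent_dim}",
            f"  hidden layers : {self.model.hidden}",
            f"  epochs        : {len(h)}",
            f"  seed          : {self.seed}",
        ]
        if len(h):
            lines.append(f"  loss (first -> last): {h['total'].iloc[0]:.4f} -> "
                         f"{h['total'].iloc[-1]:.4f}")
        return "\n".join(lines)

    def plot_loss(self, ax=None):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        for col in ("total", "recon", "kl"):
            ax.plot(self.history["epoch"], self.history[col], label=col)
        ax.set_xlabel("epoch"); ax.set_ylabel("loss"); ax.legend()
        return ax

    # -- persistence ----------------------------------------------------------
    def save(self, path) -> None:
        meta = {
            "latent_dim": self.latent_dim,
            "hidden": list(self.model.hidden),
            "n_genes": self.n_genes,
            "kl_weight": self.model.kl_weight,
            "seed": self.seed,
            "gene_hash": self.gene_hash,
            "gene_names": self.gene_names,
        }
        np.savez(
            path,
            meta=json.dumps(meta),
            latent_mean=self.latent_norm.mean,
            latent_std=self.latent_norm.std,
            history=self.history.to_numpy(),
            **{f"param:{k}": v for k, v in self.params.items()},
        )

    @classmethod
    def load(cls, path) -> "VAEResults":
        with np.load(path, allow_pickle=False) as f:
            meta = json.loads(str(f["meta"]))
            params = {k.split(":", 1)[1]: f[k] for k in f.files if k.startswith("param:")}
            norm = LatentNormalizer(f["latent_mean"], f["latent_std"])
            history = pd.DataFrame(f["history"], columns=["epoch", "total", "recon", "kl"])
        model = GaussianVAE(np.zeros((1, meta["n_genes"])), latent_dim=meta["latent_dim"],
                            hidden=tuple(meta["hidden"]), kl_weight=meta["kl_weight"],
                            seed=meta["seed"])
        model.gene_names = meta["gene_names"]
        res = cls(model, {k: np.array(v) for k, v in params.items()}, history,
                  latent_norm=norm)
        res.gene_names = meta["gene_names"]
        res.gene_hash = meta["gene_hash"]
        return res


@dataclass
class TrainReport:
    """Compact training record exported alongside checkpoints."""

    epochs: int
    seed: int
    final_total: float
    final_recon: float
    final_kl: float

    @classmethod
    def from_results(cls, res: VAEResults) -> "TrainReport":
        h = res.history
        if len(h) == 0:
            return cls(0, res.seed, float("nan"), float("nan"), float("nan"))
        return cls(len(h), res.seed, float(h["total"].iloc[-1]),
                   float(h["recon"].iloc[-1]), float(h["kl"].iloc[-1]))
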