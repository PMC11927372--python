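"""Denoising diffusion on VAE latents (DDPM).

Forward process: a fixed Markov chain of Gaussian perturbations

    q(z_t | z_{t-1}) = N(√(1−β_t) z_{t-1}, β_t I),  t = 1..T

with the closed-form marginal q(z_t | z_0) = N(√ᾱ_t z_0, (1−ᾱ_t) I),
ᾱ_t = Π_{s≤t} (1−β_s). The reverse process is learned by a noise-prediction
network ε_θ(z_t, t) trained on the simplified objective

    L = E_{t, z_0, ε} ‖ ε − ε_θ(√ᾱ_t z_0 + √(1−ᾱ_t) ε, t) ‖²

with t uniform on {1..T} and ε ~ N(0, I). Ancestral sampling applies

    z_{t-1} = (1/√α_t) (z_t − (1−α_t)/√(1−ᾱ_t) ε_θ(z_t, t)) + σ_t J

with σ_t² = β_t and σ_1 = 0 (no noise at the final step). An exponential
moving average of the network weights (decay 0.999) is tracked during
training and used for all inference by default.

β schedules: linear, quadratic (equally spaced in √β), and a sigmoid ramp;
β ranges over [1e-5, 0.5e-2] by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._nn import Adam, Params, clone_params, init_mlp, mlp_backward, mlp_forward

SCHEDULE_KINDS = ("linear", "quadratic", "sigmoid")
DEFAULT_BETA_MIN = 1e-5
DEFAULT_BETA_MAX = 0.5e-2


@dataclass(frozen=True)
class NoiseSchedule:
    """β/α/ᾱ arrays defining the forward diffusion process (t = 1..T)."""

    kind: str
    T: int
    beta_min: float
    beta_max: float
    betas: np.ndarray = field(repr=False)
    alphas: np.ndarray = field(repr=False)
    alpha_bars: np.ndarray = field(repr=False)

    def _check_t(self, t: int) -> int:
        t = int(t)
        if not 1 <= t <= self.T:
            raise IndexError(f"t={t} outside 1..{self.T}")
        return t

    def beta(self, t: int) -> float:
        return float(self.betas[self._check_t(t) - 1])

    def alpha(self, t: int) -> float:
        return float(self.alphas[self._check_t(t) - 1])

    def alpha_bar(self, t: int) -> float:
        return float(self.alpha_bars[self._check_t(t) - 1])


def build_schedule(kind: str = "linear", T: int = 1000,
                   beta_min: float = DEFAULT_BETA_MIN,
                   beta_max: float = DEFAULT_BETA_MAX) -> NoiseSchedule:
    """Construct a noise schedule of the given kind."""
    if kind not in SCHEDULE_KINDS:
        raise ValueError(f"kind must be one of {SCHEDULE_KINDS}, got {kind!r}")
    if T < 1:
        raise ValueError("T must be >= 1")
    if not (0.0 < beta_min <= beta_max < 1.0):
        raise ValueError("need 0 < beta_min <= beta_max < 1")
    if T == 1 or beta_min == beta_max:
        betas = np.full(T, beta_min)
    elif kind == "linear":
        betas = np.linspace(beta_min, beta_max, T)
    elif kind == "quadratic":
        betas = np.linspace(np.sqrt(beta_min), np.sqrt(beta_max), T) ** 2
    else:  # sigmoid ramp over [-6, 6], rescaled exactly onto [beta_min, beta_max]
        s = 1.0 / (1.0 + np.exp(-np.linspace(-6.0, 6.0, T)))
        s = (s - s[0]) / (s[-1] - s[0])
        betas = beta_min + (beta_max - beta_min) * s
    alphas = 1.0 - betas
    alpha_bars = np.cumprod(alphas)
    return NoiseSchedule(kind=kind, T=T, beta_min=beta_min, beta_max=beta_max,
                         betas=betas, alphas=alphas, alpha_bars=alpha_bars)


def q_sample(z0: np.ndarray, t: int, eps: np.ndarray, schedule: NoiseSchedule) -> np.ndarray:
    """Closed-form forward draw: √ᾱ_t z0 + √(1−ᾱ_t) ε."""
    z0 = np.asarray(z0, dtype=float)
    eps = np.asarray(eps, dtype=float)
    if eps.shape != z0.shape:
        raise ValueError(f"eps shape {eps.shape} != z0 shape {z0.shape}")
    ab = schedule.alpha_bar(t)
    return np.sqrt(ab) * z0 + np.sqrt(1.0 - ab) * eps


def q_step(z_prev: np.ndarray, t: int, eps: np.ndarray, schedule: NoiseSchedule) -> np.ndarray:
    """One-step forward kernel: √(1−β_t) z_{t-1} + √β_t ε."""
    b = schedule.beta(t)
    return np.sqrt(1.0 - b) * np.asarray(z_prev, float) + np.sqrt(b) * np.asarray(eps, float)


def diffuse_to(z: np.ndarray, t_mix: int, eps: np.ndarray, schedule: NoiseSchedule) -> np.ndarray:
    """Map a latent into the diffusion prior space at step ``t_mix``.

    Alias of :func:`q_sample`, named for its role in interpolation and
    perturbation arithmetic.
    """
    return q_sample(z, t_mix, eps, schedule)


def terminal_kl(schedule: NoiseSchedule, z0: np.ndarray) -> dict:
    """Closed-form KL(q(z_T|z0) ‖ N(0, I)) in nats (total and per dimension).

    q(z_T|z0) = N(√ᾱ_T z0, (1−ᾱ_T) I), so the KL is
    ½ [ d(σ² − 1 − log σ²) + ᾱ_T ‖z0‖² ] with σ² = 1 − ᾱ_T. The
    per-dimension value is the scale-free diagnostic of how close the chain
    is to its stationary standard Gaussian.
    """
    z0 = np.atleast_1d(np.asarray(z0, dtype=float))
    d = z0.size
    ab = schedule.alpha_bar(schedule.T)
    s2 = 1.0 - ab
    total = 0.5 * (d * (s2 - 1.0 - np.log(s2)) + ab * float(z0 @ z0))
    return {"total": float(total), "per_dim": float(total / d), "alpha_bar_T": float(ab)}


def ema_update(shadow, current, decay: float):
    """shadow' = decay·shadow + (1−decay)·current, elementwise.

    Accepts either plain arrays or flat parameter dicts.
    """
    if not 0.0 <= decay < 1.0:
        raise ValueError(f"decay must be in [0, 1), got {decay}")
    if isinstance(shadow, dict):
        if set(shadow) != set(current):
            raise ValueError("shadow and current parameter sets differ")
        return {k: ema_update(shadow[k], current[k], decay) for k in shadow}
    shadow = np.asarray(shadow, dtype=float)
    current = np.asarray(current, dtype=float)
    if shadow.shape != current.shape:
        raise ValueError(f"shape mismatch {shadow.shape} vs {current.shape}")
    return decay * shadow + (1.0 - decay) * current


def time_embedding(t, dim: int) -> np.ndarray:
    """Sinusoidal timestep features (transformer-style frequencies)."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    half = dim // 2
    freqs = np.exp(-np.log(10000.0) * np.arange(half) / max(half, 1))
    args = t[:, None] * freqs[None, :]
    emb = np.concatenate([np.sin(args), np.cos(args)], axis=1)
    if emb.shape[1] < dim:  # odd dim: pad
        emb = np.pad(emb, ((0, 0), (0, dim - emb.shape[1])))
    return emb


class LatentDiffusion:
    """Diffusion model over (normalised) VAE latents.

    The noise-prediction network is an MLP on the concatenation of the
    latent vector and a sinusoidal embedding of t (flat latent inputs need
    no U-Net). ``fit`` returns :class:`DiffusionResults`.
    """

    def __init__(self, Z, schedule: NoiseSchedule | None = None,
                 hidden: tuple = (128, 128), time_dim: int = 32, seed: int = 0):
        self.Z = np.atleast_2d(np.asarray(Z, dtype=float))
        self.d_latent = self.Z.shape[1]
        self.schedule = schedule or build_schedule()
        self.hidden = tuple(int(h) for h in hidden)
        self.time_dim = int(time_dim)
        self.seed = int(seed)

    def _init_params(self, rng: np.random.Generator) -> Params:
        sizes = [self.d_latent + self.time_dim, *self.hidden, self.d_latent]
        return init_mlp(sizes, rng, name="eps")

    def _forward(self, params: Params, z_t: np.ndarray, t):
        temb = time_embedding(np.broadcast_to(t, (z_t.shape[0],)), self.time_dim)
        x = np.concatenate([z_t, temb], axis=1)
        out, cache = mlp_forward(params, x, name="eps")
        return out, cache

    def fit(self, epochs: int = 200, batch_size: int = 128, lr: float = 1e-3,
            ema_decay: float = 0.999) -> "DiffusionResults":
        """Minimise the ε-prediction objective; EMA shadow updated per step."""
        if not 0.0 <= ema_decay < 1.0:
            raise ValueError("ema_decay must be in [0, 1)")
        ss = np.random.SeedSequence(self.seed)
        init_rng, train_rng = [np.random.default_rng(s) for s in ss.spawn(2)]
        params = self._init_params(init_rng)
        shadow = clone_params(params)
        opt = Adam(params, lr=lr)
        sched = self.schedule
        n = self.Z.shape[0]
        trace = []
        step = 0
        for epoch in range(epochs):
            order = train_rng.permutation(n)
            running = 0.0
            nb = 0
            for start in range(0, n, batch_size):
                idx = order[start:start + batch_size]
                z0 = self.Z[idx]
                t = train_rng.integers(1, sched.T + 1, size=len(idx))
                eps = train_rng.standard_normal(z0.shape)
                ab = sched.alpha_bars[t - 1][:, None]
                z_t = np.sqrt(ab) * z0 + np.sqrt(1.0 - ab) * eps
                pred, cache = self._forward(params, z_t, t)
                resid = pred - eps
                loss = float(np.mean(np.sum(resid * resid, axis=1)))
                if not np.isfinite(loss):
                    raise RuntimeError(f"non-finite diffusion loss at step {step}")
                grads, _ = mlp_backward(params, cache, 2.0 * resid / len(idx), name="eps")
                opt.step(params, grads)
                shadow = ema_update(shadow, params, ema_decay)
                running += loss
                nb += 1
                step += 1
            trace.append((epoch, running / nb))
        history = pd.DataFrame(trace, columns=["epoch", "loss"])
        return DiffusionResults(self, params, shadow, history, ema_decay)


class DiffusionResults:
    """Fitted diffusion model: ε_θ (raw + EMA weights), schedule, sampler."""

    def __init__(self, model: LatentDiffusion, params: Params, ema_params: Params,
                 history: pd.DataFrame, ema_decay: float, vae_hash: str | None = None):
        self.model = model
        self.params = params
        self.ema_params = ema_params
        self.history = history
        self.ema_decay = float(ema_decay)
        self.schedule = model.schedule
        self.d_latent = model.d_latent
        self.seed = model.seed
        self.vae_hash = vae_hash

    def _weights(self, use_ema: bool) -> Params:
        return self.ema_params if use_ema else self.params

    def predict_eps(self, z_t: np.ndarray, t, use_ema: bool = True) -> np.ndarray:
        z_t = np.atleast_2d(np.asarray(z_t, dtype=float))
        if z_t.shape[1] != self.d_latent:
            raise ValueError(f"expected latent width {self.d_latent}, got {z_t.shape[1]}")
        out, _ = self.model._forward(self._weights(use_ema), z_t, t)
        return out

    def p_sample_step(self, z_t: np.ndarray, t: int, noise: np.ndarray | None = None,
                      rng: np.random.Generator | None = None,
                      use_ema: bool = True) -> np.ndarray:
        """One reverse (ancestral) update z_t -> z_{t-1}; σ_1 = 0."""
        sched = self.schedule
        t = sched._check_t(t)
        z_t = np.atleast_2d(np.asarray(z_t, dtype=float))
        a = sched.alpha(t)
        ab = sched.alpha_bar(t)
        eps_hat = self.predict_eps(z_t, t, use_ema=use_ema)
        mean = (z_t - (1.0 - a) / np.sqrt(1.0 - ab) * eps_hat) / np.sqrt(a)
        if t == 1:
            return mean
        if noise is None:
            rng = rng or np.random.default_rng()
            noise = rng.standard_normal(z_t.shape)
        return mean + np.sqrt(sched.beta(t)) * np.asarray(noise, dtype=float)

    def denoise_from(self, z_t: np.ndarray, t_start: int,
                     noise_record: list[np.ndarray] | None = None,
                     rng: np.random.Generator | None = None,
                     use_ema: bool = True) -> np.ndarray:
        """Run the reverse process from step ``t_start`` down to 1.

        ``noise_record``, when given, supplies the J draw for each step
        t = t_start..2 (shared-noise sampling); each entry may be a single
        latent row broadcast across the batch.
        """
        t_start = self.schedule._check_t(t_start)
        z = np.atleast_2d(np.asarray(z_t, dtype=float))
        for i, t in enumerate(range(t_start, 0, -1)):
            noise = None
            if t > 1 and noise_record is not None:
                noise = np.broadcast_to(noise_record[i], z.shape)
            z = self.p_sample_step(z, t, noise=noise, rng=rng, use_ema=use_ema)
        return z

    def make_noise_record(self, t_start: int, rng: np.random.Generator) -> list[np.ndarray]:
        """Draw one J per reverse step (fixed stochasticity for sampling)."""
        return [rng.standard_normal((1, self.d_latent))
                for t in range(t_start, 1, -1)]

    def generate(self, n: int, seed: int | None = None, use_ema: bool = True) -> np.ndarray:
        """Ancestral sampling: z_T ~ N(0, I), then T reverse steps."""
        if n == 0:
            return np.zeros((0, self.d_latent))
        rng = np.random.default_rng(self.seed if seed is None else seed)
        z = rng.standard_normal((n, self.d_latent))
        for t in range(self.schedule.T, 0, -1):
            z = self.p_sample_step(z, t, rng=rng, use_ema=use_ema)
        return z

    def diffuse_to(self, z: np.ndarray, t_mix: int, eps: np.ndarray) -> np.ndarray:
        return diffuse_to(z, t_mix, eps, self.schedule)

    def loss_on(self, Z: np.ndarray, seed: int = 0, use_ema: bool = True) -> float:
        """Monte-Carlo ε-prediction loss on a latent matrix."""
        rng = np.random.default_rng(seed)
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        t = rng.integers(1, self.schedule.T + 1, size=Z.shape[0])
        eps = rng.standard_normal(Z.shape)
        ab = self.schedule.alpha_bars[t - 1][:, None]
        z_t = np.sqrt(ab) * Z + np.sqrt(1.0 - ab) * eps
        pred, _ = self.model._forward(self._weights(use_ema), z_t, t)
        return float(np.mean(np.sum((pred - eps) ** 2, axis=1)))

    def summary(self) -> str:
        h = self.history
        lines = [
            "Latent diffusion results",
            f"  latent dim : {self.d_latent}",
            f"  schedule   : {self.schedule.kind}, T={self.schedule.T}, "
            f"beta in [{self.schedule.beta_min:g}, {self.schedule.beta_max:g}]",
            f"  EMA decay  : {self.ema_decay}",
            f"  epochs     : {len(h)}",
            f"  seed       : {self.seed}",
        ]
        if len(h):
            lines.append(f"  loss (first -> last): {h['loss'].iloc[0]:.4f} -> "
                         f"{h['loss'].iloc[-1]:.4f}")
        return "\n".join(lines)

    def save(self, path) -> None:
        meta = {
            "d_latent": self.d_latent,
            "hidden": list(self.model.hidden),
            "time_dim": self.model.time_dim,
            "schedule": {"kind": self.schedule.kind, "T": self.schedule.T,
                         "beta_min": self.schedule.beta_min,
                         "beta_max": self.schedule.beta_max},
            "ema_decay": self.ema_decay,
            "seed": self.seed,
            "vae_hash": self.vae_hash,
        }
        np.savez(
            path,
            meta=json.dumps(meta),
            history=self.history.to_numpy(),
            **{f"param:{k}": v for k, v in self.params.items()},
            **{f"ema:{k}": v for k, v in self.ema_params.items()},
        )

    @classmethod
    def load(cls, path) -> "DiffusionResults":
        with np.load(path, allow_pickle=False) as f:
            meta = json.loads(str(f["meta"]))
            params = {k.split(":", 1)[1]: np.array(f[k]) for k in f.files
                      if k.startswith("param:")}
            ema = {k.split(":", 1)[1]: np.array(f[k]) for k in f.files
                   if k.startswith("ema:")}
            history = pd.DataFrame(f["history"], columns=["epoch", "loss"])
        s = meta["schedule"]
        sched = build_schedule(s["kind"], s["T"], s["beta_min"], s["beta_max"])
        model = LatentDiffusion(np.zeros((1, meta["d_latent"])), schedule=sched,
                                hidden=tuple(meta["hidden"]),
                                time_dim=meta["time_dim"], seed=meta["seed"])
        return cls(model, params, ema, history, meta["ema_decay"],
                   vae_hash=meta.get("vae_hash"))
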