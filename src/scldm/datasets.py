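"""Synthetic scRNA-seq generators with known ground truth.

Three archetypes mirror the structures the models are meant to handle:

``clusters``
    Discrete cell types. Each cluster has a Gaussian programme in a
    low-dimensional factor space which is mapped to genes through a fixed
    random loading; counts are Poisson draws from exponentiated log-rates.

``trajectory``
    A differentiation axis between two named endpoint states. Every gene
    follows a response curve in pseudo-position λ ∈ [0, 1]: most genes are
    linear, a designated set of "master" genes switch logistically with a
    steep slope early on the axis. The master set is the recoverable ground
    truth for velocity ranking.

``perturbation``
    Paired control/stimulated conditions over several cell types: a shared
    additive log-scale response on a subset of genes, modulated by a
    per-cell-type factor.

All archetypes share the same noise model: log-normal cell size factors,
Poisson counts, independent Bernoulli dropout. Everything is a pure
function of ``GeneratorSpec.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import anndata as ad
import numpy as np
import pandas as pd

ARCHETYPES = ("clusters", "trajectory", "perturbation")


@dataclass
class GeneratorSpec:
    """Parameters of the synthetic generator.

    Default sizes follow the smallest real dataset the models target
    (zebrafish hematopoiesis scale: 1390 cells, 1845 genes).
    """

    n_cells: int = 1390
    n_genes: int = 1845
    archetype: str = "clusters"
    seed: int = 0

    # clusters / perturbation: factor-space geometry
    n_clusters: int = 2
    weights: Optional[tuple] = None          # mixing weights, must sum to 1
    n_factors: int = 8
    center_scale: float = 2.0                # sd of cluster centres per factor
    within_cluster_sd: float = 0.5           # cell scatter around its centre

    # trajectory
    n_master_genes: int = 20
    master_switch_range: tuple = (0.02, 0.18)  # logistic midpoints in λ
    master_slope: float = 30.0                 # logistic steepness (per λ)
    master_amplitude: float = 2.5              # |log-scale| switch size
    traj_program_sd: float = 0.8               # sd of linear genes' endpoint diff

    # perturbation
    n_celltypes: int = 3
    response_frac: float = 0.15              # fraction of genes that respond
    response_scale: float = 1.0              # amplitude multiplier of the shift
    modulation_sd: float = 0.2               # per-cell-type response modulation
    stim_fraction: float = 0.5               # fraction of stimulated cells

    # noise model
    base_logmean_range: tuple = (-2.0, 1.5)  # per-gene baseline log-rate
    sigma: float = 0.3                       # log-normal expression noise
    dropout: float = 0.3                     # Bernoulli zeroing rate
    libsize_sd: float = 0.3                  # sd of log cell size factors

    def validate(self) -> None:
        problems = []
        if self.n_cells < 0:
            problems.append("n_cells must be >= 0")
        if self.n_genes < 1:
            problems.append("n_genes must be >= 1")
        if self.archetype not in ARCHETYPES:
            problems.append(f"archetype must be one of {ARCHETYPES}")
        if not (0.0 <= self.dropout < 1.0):
            problems.append("dropout must be in [0, 1)")
        if self.weights is not None:
            if len(self.weights) != self.n_clusters:
                problems.append("weights length must equal n_clusters")
            elif abs(sum(self.weights) - 1.0) > 1e-8:
                problems.append("weights must sum to 1")
        if self.archetype == "trajectory":
            lo, hi = self.master_switch_range
            if not (0.0 <= lo < hi <= 1.0):
                problems.append("master_switch_range must be ordered within [0, 1]")
            if self.n_master_genes > self.n_genes:
                problems.append("n_master_genes must be <= n_genes")
        if self.archetype == "perturbation" and not (0.0 < self.stim_fraction < 1.0):
            problems.append("stim_fraction must be in (0, 1)")
        if problems:
            raise ValueError("invalid GeneratorSpec: " + "; ".join(problems))


@dataclass
class GroundTruth:
    """Everything a downstream harness needs to score a method's output."""

    archetype: str
    gene_names: list = field(default_factory=list)
    labels: Optional[np.ndarray] = None          # cluster / cell-type per cell
    lambdas: Optional[np.ndarray] = None         # trajectory position per cell
    # trajectory curve parameters (per gene)
    base_log: Optional[np.ndarray] = None
    delta_log: Optional[np.ndarray] = None
    curve_kind: Optional[np.ndarray] = None      # "linear" | "logistic"
    switch_midpoint: Optional[np.ndarray] = None
    switch_slope: Optional[np.ndarray] = None
    master_genes: Optional[list] = None
    # perturbation
    condition: Optional[np.ndarray] = None
    response: Optional[np.ndarray] = None        # shared per-gene log shift
    modulation: Optional[dict] = None            # cell type -> multiplier

    def trajectory_log_expression(self, lam: np.ndarray) -> np.ndarray:
        """Noiseless log-rate programme on a λ grid (len(lam) × genes).

        The curves that generated the data, evaluated without sampling
        noise — the oracle path for velocity-ranking checks.
        """
        if self.archetype != "trajectory":
            raise ValueError("trajectory curves only exist for the trajectory archetype")
        lam = np.asarray(lam, dtype=float)[:, None]
        c = np.where(
            self.curve_kind == "logistic",
            1.0 / (1.0 + np.exp(-self.switch_slope[None, :] * (lam - self.switch_midpoint[None, :]))),
            lam,
        )
        return self.base_log[None, :] + self.delta_log[None, :] * c


def _finish_counts(log_mu: np.ndarray, spec: GeneratorSpec, rng: np.random.Generator) -> np.ndarray:
    n = log_mu.shape[0]
    log_mu = log_mu + rng.normal(0.0, spec.sigma, size=log_mu.shape)
    size = np.exp(rng.normal(0.0, spec.libsize_sd, size=(n, 1)))
    counts = rng.poisson(np.exp(log_mu) * size).astype(float)
    if spec.dropout > 0:
        counts *= rng.random(counts.shape) >= spec.dropout
    return counts


def _gene_names(n: int) -> list:
    return [f"gene_{i:05d}" for i in range(n)]


def _cell_ids(n: int) -> list:
    return [f"cell_{i:05d}" for i in range(n)]


def generate_dataset(spec: GeneratorSpec) -> tuple[ad.AnnData, GroundTruth]:
    """Draw one dataset; returns raw counts (AnnData) plus its ground truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    genes = _gene_names(spec.n_genes)
    base = rng.uniform(*spec.base_logmean_range, size=spec.n_genes)

    if spec.n_cells == 0:
        adata = ad.AnnData(
            X=np.zeros((0, spec.n_genes)),
            obs=pd.DataFrame(index=pd.Index([], name="cell_id")),
            var=pd.DataFrame(index=pd.Index(genes, name="gene")),
        )
        return adata, GroundTruth(archetype=spec.archetype, gene_names=genes)

    if spec.archetype == "clusters":
        adata, truth = _make_clusters(spec, rng, base, n_groups=spec.n_clusters,
                                      weights=spec.weights, key="cell_type",
                                      prefix="cluster")
    elif spec.archetype == "trajectory":
        adata, truth = _make_trajectory(spec, rng, base)
    else:
        adata, truth = _make_perturbation(spec, rng, base)
    truth.gene_names = genes
    adata.uns["generator"] = {k: (list(v) if isinstance(v, tuple) else v)
                              for k, v in asdict(spec).items()}
    return adata, truth


def _factor_log_mu(spec, rng, base, labels, n_groups):
    centers = rng.normal(0.0, spec.center_scale, size=(n_groups, spec.n_factors))
    loadings = rng.normal(0.0, 1.0 / np.sqrt(spec.n_factors),
                          size=(spec.n_factors, spec.n_genes))
    u = centers[labels] + rng.normal(0.0, spec.within_cluster_sd,
                                     size=(len(labels), spec.n_factors))
    return base[None, :] + u @ loadings


def _make_clusters(spec, rng, base, n_groups, weights, key, prefix):
    w = np.full(n_groups, 1.0 / n_groups) if weights is None else np.asarray(weights)
    labels = rng.choice(n_groups, size=spec.n_cells, p=w)
    log_mu = _factor_log_mu(spec, rng, base, labels, n_groups)
    counts = _finish_counts(log_mu, spec, rng)
    names = np.array([f"{prefix}_{k}" for k in range(n_groups)])
    obs = pd.DataFrame({key: pd.Categorical(names[labels])},
                       index=pd.Index(_cell_ids(spec.n_cells), name="cell_id"))
    adata = ad.AnnData(X=counts, obs=obs,
                       var=pd.DataFrame(index=pd.Index(_gene_names(spec.n_genes), name="gene")))
    return adata, GroundTruth(archetype="clusters", labels=names[labels])


def _make_trajectory(spec, rng, base):
    lam = np.sort(rng.uniform(0.0, 1.0, size=spec.n_cells))
    kind = np.array(["linear"] * spec.n_genes, dtype=object)
    master_idx = rng.choice(spec.n_genes, size=spec.n_master_genes, replace=False)
    kind[master_idx] = "logistic"
    delta = rng.normal(0.0, spec.traj_program_sd, size=spec.n_genes)
    delta[master_idx] = rng.choice([-1.0, 1.0], size=spec.n_master_genes) * spec.master_amplitude
    mid = np.full(spec.n_genes, 0.5)
    mid[master_idx] = rng.uniform(*spec.master_switch_range, size=spec.n_master_genes)
    slope = np.full(spec.n_genes, spec.master_slope)

    genes = _gene_names(spec.n_genes)
    truth = GroundTruth(
        archetype="trajectory", lambdas=lam, base_log=base, delta_log=delta,
        curve_kind=np.asarray(kind), switch_midpoint=mid, switch_slope=slope,
        master_genes=[genes[i] for i in sorted(master_idx)],
    )
    log_mu = truth.trajectory_log_expression(lam)
    counts = _finish_counts(log_mu, spec, rng)
    state = np.where(lam < 0.5, "state_a", "state_b")
    obs = pd.DataFrame(
        {"lambda_true": lam, "cell_type": pd.Categorical(state)},
        index=pd.Index(_cell_ids(spec.n_cells), name="cell_id"),
    )
    adata = ad.AnnData(X=counts, obs=obs,
                       var=pd.DataFrame(index=pd.Index(genes, name="gene")))
    truth.gene_names = genes
    return adata, truth


def _make_perturbation(spec, rng, base):
    labels = rng.choice(spec.n_celltypes, size=spec.n_cells)
    log_mu = _factor_log_mu(spec, rng, base, labels, spec.n_celltypes)
    stim = rng.random(spec.n_cells) < spec.stim_fraction

    n_resp = max(1, int(round(spec.response_frac * spec.n_genes)))
    # responsive genes are drawn from the expressed half so the programmed
    # shift stays identifiable after count sampling and log transforms
    expressed = np.flatnonzero(base >= np.quantile(base, 0.6))
    resp_idx = rng.choice(expressed, size=min(n_resp, expressed.size), replace=False)
    response = np.zeros(spec.n_genes)
    response[resp_idx] = (rng.choice([-1.0, 1.0], size=n_resp)
                          * rng.uniform(0.5, 1.5, size=n_resp) * spec.response_scale)
    mod = 1.0 + spec.modulation_sd * rng.standard_normal(spec.n_celltypes)
    mod = np.clip(mod, 0.2, None)
    log_mu = log_mu + stim[:, None] * response[None, :] * mod[labels][:, None]

    counts = _finish_counts(log_mu, spec, rng)
    type_names = np.array([f"type_{k}" for k in range(spec.n_celltypes)])
    cond = np.where(stim, "stimulated", "control")
    obs = pd.DataFrame(
        {"cell_type": pd.Categorical(type_names[labels]),
         "condition": pd.Categorical(cond, categories=["control", "stimulated"])},
        index=pd.Index(_cell_ids(spec.n_cells), name="cell_id"),
    )
    adata = ad.AnnData(X=counts, obs=obs,
                       var=pd.DataFrame(index=pd.Index(_gene_names(spec.n_genes), name="gene")))
    truth = GroundTruth(
        archetype="perturbation", labels=type_names[labels], condition=cond,
        response=response,
        modulation={type_names[k]: float(mod[k]) for k in range(spec.n_celltypes)},
    )
    return adata, truth
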