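"""Pipeline configuration, provenance and stage orchestration.

Training is strictly two-stage: the VAE is fitted first, then the
diffusion model is fitted on the frozen, normalised VAE latents — a DDM is
never trained against a VAE whose preprocessing fingerprint (hash of the
gene list) differs from the input's. Every artifact embeds the resolved
configuration and seeds so a run is reproducible from its outputs alone.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict

from . import io as io_mod
from .datasets import GeneratorSpec, generate_dataset
from .diffusion import DiffusionResults, LatentDiffusion, build_schedule
from .metrics import compare_priors
from .vae import GaussianVAE, VAEResults, TrainReport, gene_fingerprint

SCHEMA_VERSION = "1"
STAGE_ORDER = ("fixture", "preprocess", "vae", "ddm", "eval")


class ProvenanceError(RuntimeError):
    """Checkpoint and input disagree about what data the model was fit on."""


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class FixtureSection(_Section):
    archetype: str = "clusters"
    n_cells: int = 1390
    n_genes: int = 1845
    n_clusters: int = 2


class PreprocessSection(_Section):
    n_hvg: int = 2000
    normalize: bool = True
    log1p: bool = True
    center: bool = True


class VAESection(_Section):
    latent_dim: int = 32
    hidden: tuple[int, ...] = (256, 128)
    kl_weight: float = 1.0
    epochs: int = 100
    batch_size: int = 128
    lr: float = 1e-3


class DDMSection(_Section):
    schedule: str = "linear"
    T: int = 1000
    beta_min: float = 1e-5
    beta_max: float = 0.5e-2
    hidden: tuple[int, ...] = (128, 128)
    time_dim: int = 32
    epochs: int = 200
    batch_size: int = 128
    lr: float = 1e-3
    ema_decay: float = 0.999


class EvalSection(_Section):
    n_samples: int = 5000
    n_bins: int = 50


class RunConfig(_Section):
    """All stage defaults in one declarative document; unknown keys rejected."""

    stages: tuple[str, ...] = ("fixture", "preprocess", "vae", "ddm")
    input: str | None = None
    seed: int = 0
    fixture: FixtureSection = FixtureSection()
    preprocess: PreprocessSection = PreprocessSection()
    vae: VAESection = VAESection()
    ddm: DDMSection = DDMSection()
    eval: EvalSection = EvalSection()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.model_validate(doc)

    def resolved(self) -> dict:
        return json.loads(self.model_dump_json())


def _stage_seed(seed: int, stage: str) -> int:
    offsets = {"fixture": 0, "vae": 1, "ddm": 2, "eval": 3}
    return int(np.random.SeedSequence((seed, offsets[stage])).generate_state(1)[0]
               % (2**31))


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute the requested stages in order; returns artifact paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = [s for s in STAGE_ORDER if s in config.stages]
    unknown = set(config.stages) - set(STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    resolved = config.resolved()
    artifacts: dict = {}

    adata = None
    if "fixture" in stages:
        spec = GeneratorSpec(archetype=config.fixture.archetype,
                             n_cells=config.fixture.n_cells,
                             n_genes=config.fixture.n_genes,
                             n_clusters=config.fixture.n_clusters,
                             seed=_stage_seed(config.seed, "fixture"))
        adata, _ = generate_dataset(spec)
        path = outdir / "raw.h5ad"
        io_mod.write_expression(adata, path, fmt="h5ad")
        artifacts["raw"] = str(path)
    elif config.input is not None:
        adata = io_mod.read_expression(config.input)
        artifacts["raw"] = str(config.input)

    if "preprocess" in stages:
        if adata is None:
            raise ValueError("preprocess stage needs a fixture stage or an input path")
        cfg = io_mod.PreprocessConfig(**config.preprocess.model_dump())
        adata = io_mod.preprocess(adata, cfg)
        adata.uns["run_config"] = json.dumps(resolved, sort_keys=True)
        path = outdir / "processed.h5ad"
        io_mod.write_expression(adata, path, fmt="h5ad")
        artifacts["processed"] = str(path)

    vae_res = None
    if "vae" in stages:
        if adata is None:
            adata = io_mod.read_expression(outdir / "processed.h5ad")
        model = GaussianVAE(adata, latent_dim=config.vae.latent_dim,
                            hidden=config.vae.hidden, kl_weight=config.vae.kl_weight,
                            seed=_stage_seed(config.seed, "vae"))
        vae_res = model.fit(epochs=config.vae.epochs,
                            batch_size=config.vae.batch_size, lr=config.vae.lr)
        path = outdir / "vae.npz"
        vae_res.save(path)
        artifacts["vae"] = str(path)
        _write_report(outdir / "vae_report.json", resolved, stage="vae",
                      report=TrainReport.from_results(vae_res).__dict__)

    ddm_res = None
    if "ddm" in stages:
        if vae_res is None:
            vae_res = VAEResults.load(outdir / "vae.npz")
        if adata is None:
            adata = io_mod.read_expression(outdir / "processed.h5ad")
        check_fingerprint(vae_res, adata)
        Z = vae_res.encode(adata)
        sched = build_schedule(config.ddm.schedule, config.ddm.T,
                               config.ddm.beta_min, config.ddm.beta_max)
        ddm = LatentDiffusion(Z, schedule=sched, hidden=config.ddm.hidden,
                              time_dim=config.ddm.time_dim,
                              seed=_stage_seed(config.seed, "ddm"))
        ddm_res = ddm.fit(epochs=config.ddm.epochs, batch_size=config.ddm.batch_size,
                          lr=config.ddm.lr, ema_decay=config.ddm.ema_decay)
        ddm_res.vae_hash = vae_res.gene_hash
        path = outdir / "ddm.npz"
        ddm_res.save(path)
        artifacts["ddm"] = str(path)
        h = ddm_res.history
        _write_report(outdir / "ddm_report.json", resolved, stage="ddm",
                      report={"epochs": len(h),
                              "final_loss": float(h["loss"].iloc[-1]),
                              "first_loss": float(h["loss"].iloc[0]),
                              "seed": ddm_res.seed})

    if "eval" in stages:
        if vae_res is None:
            vae_res = VAEResults.load(outdir / "vae.npz")
        if ddm_res is None:
            ddm_res = DiffusionResults.load(outdir / "ddm.npz")
        if adata is None:
            adata = io_mod.read_expression(outdir / "processed.h5ad")
        check_fingerprint(vae_res, adata)
        res = compare_priors(vae_res, ddm_res, adata,
                             n_samples=config.eval.n_samples,
                             seed=_stage_seed(config.seed, "eval"),
                             n_bins=config.eval.n_bins)
        _write_report(outdir / "eval_report.json", resolved, stage="eval",
                      report={"tvd_ddm": res["tvd_ddm"],
                              "tvd_vae_prior": res["tvd_vae_prior"],
                              "margin": res["margin"]})
        artifacts["eval"] = str(outdir / "eval_report.json")

    return artifacts


def check_fingerprint(vae_res: VAEResults, adata) -> None:
    """Refuse to pair a checkpoint with data it was not preprocessed for."""
    if vae_res.gene_hash is None:
        return
    actual = gene_fingerprint(list(adata.var_names))
    if actual != vae_res.gene_hash:
        raise ProvenanceError(
            "gene-list fingerprint of the input does not match the VAE "
            f"checkpoint ({actual[:12]} != {vae_res.gene_hash[:12]}); "
            "re-run preprocessing or retrain the VAE")


def _write_report(path, resolved_config: dict, stage: str, report: dict) -> None:
    payload = {"schema_version": SCHEMA_VERSION, "stage": stage,
               "report": report, "config": resolved_config}
    Path(path).write_text(json.dumps(payload, sort_keys=True, indent=1) + "\n")
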