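"""Reading, writing and preprocessing of expression matrices.

The in-memory container is :class:`anndata.AnnData`, cells × genes
everywhere. Optional per-cell metadata lives in ``.obs`` under the keys
``cell_type`` and ``condition``; the record of applied preprocessing steps
is kept in ``.uns["preprocess"]``.

Preprocessing follows the standard single-cell recipe: per-cell
library-size normalization (to the median total count), log1p, selection
of the top highly variable genes by normalized dispersion, then per-gene
centering. HVG ties are broken lexicographically by gene name so the
selected set is a pure function of the matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

METADATA_COLUMNS = ("cell_type", "condition")


class ExpressionFormatError(ValueError):
    """A file could not be parsed in the named format."""


class AlignmentError(ValueError):
    """Matrix dimensions disagree with sidecar metadata."""


class PreprocessError(ValueError):
    """Input violates a preprocessing precondition."""


@dataclass
class PreprocessConfig:
    n_hvg: int = 2000
    normalize: bool = True
    log1p: bool = True
    center: bool = True


def read_expression(path, fmt: str | None = None, obs_path=None) -> ad.AnnData:
    """Read an expression matrix as cells × genes.

    Parameters
    ----------
    path
        File (h5ad, csv) or directory (mtx with ``genes.tsv``/``barcodes.tsv``).
    fmt
        ``"h5ad"``, ``"mtx"`` or ``"csv"``; inferred from the path when omitted.
    obs_path
        Optional TSV of per-cell metadata (index = cell ids) merged into
        ``.obs``; missing metadata columns are simply absent, never an error.
    """
    path = Path(path)
    if fmt is None:
        if path.is_dir():
            fmt = "mtx"
        elif path.suffix == ".h5ad":
            fmt = "h5ad"
        elif path.suffix in (".csv", ".txt"):
            fmt = "csv"
        else:
            raise ExpressionFormatError(f"cannot infer format from {path.name!r}")
    if fmt == "h5ad":
        adata = _read_h5ad(path)
    elif fmt == "mtx":
        adata = _read_mtx_dir(path)
    elif fmt == "csv":
        adata = _read_csv(path)
    else:
        raise ExpressionFormatError(f"unknown format {fmt!r}")

    if obs_path is not None:
        meta = pd.read_csv(obs_path, sep="\t", index_col=0)
        if len(meta) != adata.n_obs:
            raise AlignmentError(
                f"metadata has {len(meta)} rows but matrix has {adata.n_obs} cells")
        for col in meta.columns:
            adata.obs[col] = meta[col].values

    if not np.isfinite(_dense(adata.X)).all():
        raise ExpressionFormatError(f"{path}: non-finite values in expression matrix")
    if adata.var_names.duplicated().any():
        dupes = adata.var_names[adata.var_names.duplicated()].tolist()[:5]
        raise ExpressionFormatError(f"{path}: duplicated gene names, e.g. {dupes}")
    if adata.n_vars and _dense(adata.X).max(initial=0.0) == 0.0:
        warnings.warn(f"{path}: expression matrix is all zeros", stacklevel=2)
    return adata


def _read_h5ad(path: Path) -> ad.AnnData:
    try:
        return ad.read_h5ad(path)
    except Exception as exc:  # noqa: BLE001 - rewrap with the offending file
        raise ExpressionFormatError(f"{path}: not a readable h5ad file ({exc})") from exc


def _read_csv(path: Path) -> ad.AnnData:
    try:
        df = pd.read_csv(path, index_col=0)
        values = df.to_numpy(dtype=float)
    except (ValueError, pd.errors.ParserError) as exc:
        raise ExpressionFormatError(f"{path}: not a numeric CSV matrix ({exc})") from exc
    return ad.AnnData(
        X=values,
        obs=pd.DataFrame(index=pd.Index(df.index.astype(str), name="cell_id")),
        var=pd.DataFrame(index=pd.Index(df.columns.astype(str), name="gene")),
    )


def _read_mtx_dir(path: Path) -> ad.AnnData:
    mtx = path / "matrix.mtx"
    try:
        mat = sp.csr_matrix(scipy.io.mmread(mtx))
    except Exception as exc:  # noqa: BLE001
        raise ExpressionFormatError(f"{mtx}: unreadable MatrixMarket file ({exc})") from exc
    genes = pd.read_csv(path / "genes.tsv", sep="\t", header=None)[0].astype(str)
    cells = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    if mat.shape == (len(genes), len(cells)) and mat.shape[0] != mat.shape[1]:
        mat = mat.T  # genes × cells on disk (CellRanger layout)
    if mat.shape != (len(cells), len(genes)):
        raise AlignmentError(
            f"{mtx}: matrix shape {mat.shape} does not match "
            f"{len(cells)} barcodes × {len(genes)} genes")
    if mat.nnz == 0:
        logger.warning("%s: matrix has zero nonzeros", mtx)
    return ad.AnnData(
        X=np.asarray(mat.todense(), dtype=float),
        obs=pd.DataFrame(index=pd.Index(cells, name="cell_id")),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )


def write_expression(adata: ad.AnnData, path, fmt: str | None = None) -> None:
    """Write cells × genes expression (h5ad, csv, or mtx directory)."""
    path = Path(path)
    if fmt is None:
        fmt = "mtx" if path.suffix == "" else path.suffix.lstrip(".")
    if fmt == "h5ad":
        adata.write_h5ad(path)
    elif fmt == "csv":
        adata.to_df().to_csv(path)
    elif fmt == "mtx":
        path.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(path / "matrix.mtx", sp.csr_matrix(np.asarray(_dense(adata.X)).T))
        pd.Series(adata.var_names).to_csv(path / "genes.tsv", sep="\t",
                                          header=False, index=False)
        pd.Series(adata.obs_names).to_csv(path / "barcodes.tsv", sep="\t",
                                          header=False, index=False)
    else:
        raise ExpressionFormatError(f"unknown format {fmt!r}")


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense() if sp.issparse(X) else X, dtype=float)


def preprocess(raw: ad.AnnData, cfg: PreprocessConfig | None = None) -> ad.AnnData:
    """Normalize → log1p → HVG selection → per-gene centering.

    Returns a new AnnData restricted to the selected genes, with the applied
    steps recorded in ``.uns["preprocess"]``. Cells with zero total counts
    are a hard error: silently dropping them would change dataset
    dimensions behind the caller's back.
    """
    import scanpy as sc

    cfg = cfg or PreprocessConfig()
    if cfg.n_hvg > raw.n_vars:
        raise PreprocessError(
            f"n_hvg={cfg.n_hvg} exceeds the {raw.n_vars} genes in the input")
    X = _dense(raw.X)
    if (cfg.normalize or cfg.log1p) and (X < 0).any():
        raise PreprocessError("negative values: normalize/log1p expect raw counts")
    totals = X.sum(axis=1)
    if cfg.normalize and (totals == 0).any():
        bad = list(np.asarray(raw.obs_names)[totals == 0][:10])
        raise PreprocessError(f"cells with zero total counts: {bad}")

    adata = raw.copy()
    adata.X = X.copy()  # never mutate the caller's matrix
    applied: dict = {}
    if cfg.normalize:
        sc.pp.normalize_total(adata, target_sum=None)  # median total count
        applied["normalize"] = {"target_sum": float(np.median(totals))}
    if cfg.log1p:
        adata.uns.pop("log1p", None)
        sc.pp.log1p(adata)
        applied["log1p"] = True
    if cfg.n_hvg < adata.n_vars:
        keep = _select_hvg(adata, cfg.n_hvg, logged=cfg.log1p)
        adata = adata[:, keep].copy()
        applied["hvg"] = {"n_hvg": cfg.n_hvg}
    if cfg.center:
        adata.X = adata.X - adata.X.mean(axis=0, keepdims=True)
        applied["center"] = True
    adata.uns["preprocess"] = applied
    return adata


def _select_hvg(adata: ad.AnnData, n_hvg: int, logged: bool = True) -> list[str]:
    """Top genes by normalized dispersion; ties broken by gene name.

    Dispersion is var/mean of the (de-logged) normalized counts, z-scored
    within quantile bins of the mean so highly expressed genes do not
    dominate — the classic single-cell HVG recipe, computed here explicitly
    so the selected set is a pure, reproducible function of the matrix at
    any gene count.
    """
    X = _dense(adata.X)
    counts = np.expm1(X) if logged else X
    mean = counts.mean(axis=0)
    var = counts.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, np.nan)
    df = pd.DataFrame({"gene": adata.var_names, "mean": mean, "disp": disp})
    n_bins = min(20, max(1, adata.n_vars // 5))
    df["bin"] = pd.qcut(df["mean"].rank(method="first"), n_bins, labels=False)
    grouped = df.groupby("bin")["disp"]
    mu, sd = grouped.transform("mean"), grouped.transform("std")
    df["disp_norm"] = ((df["disp"] - mu) / sd.replace(0.0, 1.0).fillna(1.0))
    order = (df.fillna({"disp_norm": -np.inf})
             .sort_values(["disp_norm", "gene"], ascending=[False, True],
                          kind="mergesort"))
    return sorted(order["gene"].head(n_hvg).tolist())


def preprocess_flags(adata: ad.AnnData) -> dict:
    """The provenance record of which preprocessing steps were applied."""
    return dict(adata.uns.get("preprocess", {}))


def config_dict(cfg: PreprocessConfig) -> dict:
    return asdict(cfg)
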