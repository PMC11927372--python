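"""Gene velocities along an interpolation path and fast-responder ranking.

The velocity of a gene is the per-step rate of change of its decoded
expression, normalised per unit λ so values do not depend on how densely
the path was sampled. Genes that must switch rapidly during a state
transition — master-regulator candidates — surface as the top absolute
velocities in the early steps; the canonical ranking takes the top 10
genes per step over the first 40 steps (400 entries). This is a distinct
concept from spliced/unspliced RNA velocity despite the shared name.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .interpolate import InterpolationPath


@dataclass
class VelocityTable:
    """genes × steps velocities (raw and optionally smoothed)."""

    gene_names: list
    lambdas: np.ndarray              # path λ grid (len = n_steps_path)
    raw: np.ndarray                  # genes × (n_steps_path - 1)
    smoothed: np.ndarray | None      # same shape, moving average over window
    window: int | None

    @property
    def n_steps(self) -> int:
        return self.raw.shape[1]

    def values(self, smoothed: bool = False) -> np.ndarray:
        if smoothed:
            if self.smoothed is None:
                raise ValueError("no smoothing window was applied")
            return self.smoothed
        return self.raw

    def to_frame(self, smoothed: bool = False) -> pd.DataFrame:
        return pd.DataFrame(self.values(smoothed), index=self.gene_names,
                            columns=[f"step_{i}" for i in range(self.n_steps)])


def gene_velocity(path: InterpolationPath, window: int | None = None) -> VelocityTable:
    """First differences of decoded expression per unit λ.

    ``window`` adds a centered moving average over that many steps
    (edge-replicated); both raw and smoothed velocities are kept.
    """
    if path.n_steps < 2:
        raise ValueError("path needs at least 2 steps")
    lam = np.asarray(path.lambdas, dtype=float)
    dlam = np.diff(lam)
    if dlam.std() > 1e-9 * max(dlam.mean(), 1e-300):
        raise ValueError("velocities require an equidistant lambda grid")
    expr = np.asarray(path.expressions, dtype=float)      # steps × genes
    raw = (np.diff(expr, axis=0) / dlam[:, None]).T       # genes × (steps-1)
    smoothed = None
    if window is not None:
        if not 1 <= window < raw.shape[1] + 1:
            raise ValueError(f"window {window} must be in 1..{raw.shape[1]}")
        from scipy.ndimage import uniform_filter1d
        smoothed = uniform_filter1d(raw, size=window, axis=1, mode="nearest")
    genes = (list(path.gene_names) if path.gene_names is not None
             else [f"g{i}" for i in range(raw.shape[0])])
    return VelocityTable(gene_names=genes, lambdas=lam, raw=raw,
                         smoothed=smoothed, window=window)


def rank_fast_responders(vt: VelocityTable, top_k_per_step: int = 10,
                         n_steps_considered: int = 40, dedupe: bool = False,
                         signed: bool = False,
                         smoothed: bool = False) -> pd.DataFrame:
    """Top-|velocity| genes per step, concatenated in step order.

    Defaults follow the canonical recipe: 10 genes over the first 40 steps,
    400 entries before deduplication. ``dedupe=True`` keeps the first
    occurrence of each gene; ``signed=True`` ranks by signed velocity
    (largest increase first) instead of magnitude.
    """
    V = vt.values(smoothed)
    n_steps = min(n_steps_considered, V.shape[1])
    if top_k_per_step < 1:
        raise ValueError("top_k_per_step must be >= 1")
    k = min(top_k_per_step, V.shape[0])
    genes = np.asarray(vt.gene_names)
    rows = []
    for step in range(n_steps):
        v = V[:, step]
        score = v if signed else np.abs(v)
        # descending score, ties broken by gene name
        order = np.lexsort((genes, -score))[:k]
        for rank, gi in enumerate(order):
            rows.append((step, rank, genes[gi], float(v[gi]), float(score[gi])))
    table = pd.DataFrame(rows, columns=["step", "rank", "gene", "velocity", "score"])
    if dedupe:
        table = table.drop_duplicates(subset="gene", keep="first").reset_index(drop=True)
    return table


def marker_by_difference(path: InterpolationPath, t_a: int, t_b: int) -> pd.DataFrame:
    """|expression(t_b) − expression(t_a)| per gene, ranked descending.

    ``t_a``/``t_b`` index the path's step grid; ties are broken by gene
    name so the ranking is deterministic.
    """
    expr = np.asarray(path.expressions, dtype=float)
    n = expr.shape[0]
    for t in (t_a, t_b):
        if not 0 <= t < n:
            raise IndexError(f"step {t} outside 0..{n - 1}")
    genes = (list(path.gene_names) if path.gene_names is not None
             else [f"g{i}" for i in range(expr.shape[1])])
    score = np.abs(expr[t_b] - expr[t_a])
    table = (pd.DataFrame({"gene": genes, "score": score})
             .sort_values(["score", "gene"], ascending=[False, True], kind="mergesort")
             .reset_index(drop=True))
    return table


def write_rnk(table: pd.DataFrame, path, score_col: str = "score") -> None:
    """Two-column ranked gene list consumable by enrichment tools."""
    table[["gene", score_col]].to_csv(path, sep="\t", header=False, index=False)
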