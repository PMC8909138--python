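"""Per-cell signature scoring.

Two scoring families drive the population calls:

* :func:`ssgsea_score` — a single-sample, rank-based running-sum enrichment
  statistic (used for the lipid-metabolism score that defines slow-cycling
  cells).
* :func:`tirosh_module_score` — expression-bin-matched control-gene scoring
  for cell-cycle programs (G1S, G2M); :func:`cell_cycle_score` sums the two
  into the combined cell-cycle score (CCS) that defines fast-cycling cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import ExpressionMatrix, GeneSet, UNIT_LOG2_TPM1, UNIT_TPM, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class CellScores:
    """One finite score per cell, with the parameters that produced it."""

    name: str
    cell_ids: list[str]
    values: np.ndarray
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.cell_ids),):
            raise ValidationError("one score per cell required")
        if not np.isfinite(self.values).all():
            raise ValidationError(f"non-finite values in score {self.name!r}")

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.cell_ids, name=self.name)

    def to_tsv(self, path: str | Path) -> None:
        params = ";".join(f"{k}={v}" for k, v in self.params.items())
        with open(path, "w") as fh:
            fh.write(f"cell_id\t{self.name}" + (f" ({params})" if params else "") + "\n")
            for c, v in zip(self.cell_ids, self.values):
                fh.write(f"{c}\t{v:.10g}\n")


def _descending_ranks(x: np.ndarray) -> np.ndarray:
    """Ascending-value ranks flipped so the highest value gets rank n.

    Ties receive average ranks, which keeps the statistic symmetric in
    tied genes.
    """
    return rankdata(x, method="average")


def ssgsea_score(
    m: ExpressionMatrix,
    gs: GeneSet,
    alpha: float = 0.25,
    normalize: bool = True,
) -> CellScores:
    """Single-sample enrichment of ``gs`` in every cell of ``m``.

    Per cell, genes are walked in order of decreasing expression.  Genes in
    the set step the running sum up by ``rank**alpha`` (normalized so the
    in-set steps total 1, with rank n for the most expressed gene); genes
    outside step it down by ``1/(G - |gs|)``.  The score is the sum of the
    running-sum difference over all positions.  With ``normalize`` the
    scores of all cells are divided by their (max - min) spread, the common
    rescaling for comparing enrichment across cells.
    """
    if m.unit not in (UNIT_TPM, UNIT_LOG2_TPM1):
        raise ValidationError(f"ssgsea_score expects TPM or LOG2_TPM1, got {m.unit}")
    present = sorted(g for g in gs.genes if m.has_gene(g))
    missing = sorted(gs.genes - set(present))
    if len(present) < 2:
        raise ValidationError(
            f"gene set {gs.name!r}: fewer than 2 member genes in matrix "
            f"(missing: {missing[:10]})"
        )
    n_genes = m.n_genes
    if len(present) == n_genes:
        raise ValidationError(f"gene set {gs.name!r} covers every gene; complement is empty")
    if missing:
        logger.warning("gene set %r: %d genes absent from matrix", gs.name, len(missing))

    in_set = np.zeros(n_genes, dtype=bool)
    for g in present:
        in_set[m._gene_index[g]] = True
    miss_step = 1.0 / (n_genes - len(present))

    scores = np.empty(m.n_cells)
    gene_idx = np.arange(n_genes)
    for j in range(m.n_cells):
        x = m.values[:, j]
        ranks = _descending_ranks(x)
        # traversal: decreasing expression, ties stable by gene index
        order = np.lexsort((gene_idx, -x))
        hits = in_set[order]
        w = ranks[order] ** alpha
        hit_steps = np.where(hits, w, 0.0)
        hit_cum = np.cumsum(hit_steps) / hit_steps.sum()
        miss_cum = np.cumsum(np.where(hits, 0.0, miss_step))
        scores[j] = float(np.sum(hit_cum - miss_cum))

    params = {"alpha": alpha, "normalize": normalize, "set": gs.name}
    if normalize:
        spread = scores.max() - scores.min()
        if spread > 0:
            scores = scores / spread
    return CellScores(f"ssgsea_{gs.name}", list(m.cell_ids), scores, params)


def tirosh_module_score(
    m: ExpressionMatrix,
    gs: GeneSet,
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed: int | np.random.Generator = 0,
) -> CellScores:
    """Expression-matched control scoring of a gene program.

    All genes are binned into ``n_bins`` groups of similar average
    expression; each program gene draws ``n_ctrl`` control genes from its
    own bin (with replacement when the bin is smaller).  The score of a
    cell is the mean expression of the program genes minus the mean over
    the pooled controls, which cancels cell-to-cell depth/complexity
    effects.
    """
    if m.unit != UNIT_LOG2_TPM1:
        raise ValidationError(f"tirosh_module_score expects LOG2_TPM1, got {m.unit}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    present = sorted(g for g in gs.genes if m.has_gene(g))
    dropped = sorted(gs.genes - set(present))
    if not present:
        raise ValidationError(f"no gene of set {gs.name!r} present in matrix")
    if dropped:
        logger.warning("module score %r: dropping absent genes %s", gs.name, dropped[:10])

    gene_mean = m.values.mean(axis=1)
    order = np.argsort(gene_mean, kind="stable")
    bin_of = np.empty(m.n_genes, dtype=int)
    for b, chunk in enumerate(np.array_split(order, n_bins)):
        bin_of[chunk] = b
    bins: dict[int, np.ndarray] = {b: np.flatnonzero(bin_of == b) for b in range(n_bins)}

    set_idx = np.array([m._gene_index[g] for g in present])
    ctrl_rows: list[np.ndarray] = []
    for gi in set_idx:
        pool = bins[bin_of[gi]]
        ctrl_rows.append(rng.choice(pool, size=n_ctrl, replace=len(pool) < n_ctrl))
    ctrl_idx = np.concatenate(ctrl_rows)

    score = m.values[set_idx].mean(axis=0) - m.values[ctrl_idx].mean(axis=0)
    params = {"n_bins": n_bins, "n_ctrl": n_ctrl, "set": gs.name}
    return CellScores(f"module_{gs.name}", list(m.cell_ids), score, params)


def cell_cycle_score(g1s: CellScores, g2m: CellScores) -> CellScores:
    """Combined cell-cycle score: CCS(cell) = G1S(cell) + G2M(cell)."""
    if g1s.cell_ids != g2m.cell_ids:
        if sorted(g1s.cell_ids) != sorted(g2m.cell_ids):
            raise ValidationError("G1S and G2M scores cover different cell sets")
        g2m_series = g2m.as_series().loc[g1s.cell_ids]
        g2m = CellScores(g2m.name, list(g1s.cell_ids), g2m_series.to_numpy(), g2m.params)
    return CellScores(
        "CCS",
        list(g1s.cell_ids),
        g1s.values + g2m.values,
        {"components": [g1s.name, g2m.name]},
    )
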