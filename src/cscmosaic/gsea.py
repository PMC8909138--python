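"""Rank-based gene-set enrichment with permutation FDR.

Used to ask which drug-target gene sets are enriched toward one end of a
differential-expression contrast (e.g. slow-cycling vs CD133-high private
cells).  The enrichment score is the signed maximum deviation of the
weighted Kolmogorov-Smirnov running sum; the null is gene-label
permutation; NES normalizes by the mean same-sign null magnitude and the
FDR follows the positive/negative NES pooling procedure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GeneSet, GeneSetCollection, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class GseaResult:
    """Enrichment of one gene set against a signed ranking."""

    set_name: str
    es: float
    nes: float
    p_perm: float
    fdr: float
    size: int

    @property
    def direction(self) -> str:
        return "A-enriched" if self.es >= 0 else "B-enriched"


def enrichment_score(
    ranking: pd.Series, genes: frozenset[str] | set[str], weight_p: float = 1.0
) -> float:
    """Signed max deviation of the weighted KS running sum.

    ``ranking`` maps gene -> signed statistic, any order; genes are walked
    from the most positive to the most negative statistic.  Hits step up by
    |statistic|^weight_p (normalized over in-set weights; with weight 0
    this is the classic unweighted KS statistic), misses step down by
    1/(G - |S|).
    """
    order = ranking.sort_values(ascending=False, kind="stable")
    stat = order.to_numpy(dtype=float)
    hits = np.array([g in genes for g in order.index], dtype=bool)
    n_hit = int(hits.sum())
    n = len(order)
    if n_hit == 0 or n_hit == n:
        raise ValidationError("gene set must be a strict, non-empty subset of the ranking")
    w = np.abs(stat) ** weight_p
    hit_w = np.where(hits, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:
        raise ValidationError("all in-set statistics are zero; ES undefined")
    p_hit = np.cumsum(hit_w) / denom
    p_miss = np.cumsum(np.where(hits, 0.0, 1.0 / (n - n_hit)))
    dev = p_hit - p_miss
    i = int(np.argmax(np.abs(dev)))
    return float(dev[i])


def gsea(
    ranking: pd.Series,
    collection: GeneSetCollection,
    weight_p: float = 1.0,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    min_size: int = 3,
    fdr_method: str = "pooling",
) -> list[GseaResult]:
    """Enrichment of every set of ``collection`` against ``ranking``.

    The null distribution is built by gene-label permutation: each of the
    ``n_perm`` draws rescores a random same-size gene set.  NES = ES / mean
    |null ES| of the same sign; p_perm is the same-sign null tail (with +1
    smoothing).  FDR follows the standard positive/negative NES pooling
    across sets; ``fdr_method="bh"`` applies Benjamini-Hochberg to the
    permutation p-values instead.
    """
    if len(collection) == 0:
        raise ValidationError("empty gene-set collection")
    if (ranking == 0).all():
        raise ValidationError("all ranking statistics are zero")
    if ranking.index.has_duplicates:
        raise ValidationError("duplicate genes in ranking")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    universe = set(ranking.index)

    tested: list[tuple[str, frozenset[str]]] = []
    for s in collection:
        inter = frozenset(s.genes & universe)
        if len(inter) < min_size:
            logger.warning("set %r: %d genes in ranking (< %d), skipped", s.name, len(inter), min_size)
            continue
        tested.append((s.name, inter))
    if not tested:
        return []

    gene_arr = np.array(sorted(universe))
    es_obs = {name: enrichment_score(ranking, genes, weight_p) for name, genes in tested}

    null_es: dict[str, np.ndarray] = {}
    for name, genes in tested:
        size = len(genes)
        es_null = np.empty(n_perm)
        for i in range(n_perm):
            rand = frozenset(rng.choice(gene_arr, size=size, replace=False))
            es_null[i] = enrichment_score(ranking, rand, weight_p)
        null_es[name] = es_null

    # normalize observed and null ES by mean same-sign null magnitude
    nes_obs: dict[str, float] = {}
    nes_null_all: list[np.ndarray] = []
    p_perm_by_set: dict[str, float] = {}
    for name, _ in tested:
        es = es_obs[name]
        nulls = null_es[name]
        pos = nulls[nulls >= 0]
        neg = nulls[nulls < 0]
        mean_pos = pos.mean() if pos.size else np.nan
        mean_neg = np.abs(neg).mean() if neg.size else np.nan

        def _norm(v: float) -> float:
            if v >= 0:
                return v / mean_pos if np.isfinite(mean_pos) and mean_pos > 0 else 0.0
            return v / mean_neg if np.isfinite(mean_neg) and mean_neg > 0 else 0.0

        nes_obs[name] = _norm(es)
        nes_null_all.append(np.array([_norm(v) for v in nulls]))
        same = pos if es >= 0 else neg
        exceed = int((np.abs(same) >= abs(es)).sum())
        p_perm_by_set[name] = (exceed + 1) / (len(same) + 1)

    pooled = np.concatenate(nes_null_all)
    results: list[GseaResult] = []
    obs_nes_values = np.array([nes_obs[name] for name, _ in tested])
    for (name, genes) in tested:
        nes = nes_obs[name]
        if fdr_method == "bh":
            fdr = np.nan  # filled after the loop
        else:
            if nes >= 0:
                frac_null = (pooled >= nes).mean() / max((pooled >= 0).mean(), 1e-12)
                frac_obs = (obs_nes_values >= nes).mean() / max((obs_nes_values >= 0).mean(), 1e-12)
            else:
                frac_null = (pooled <= nes).mean() / max((pooled < 0).mean(), 1e-12)
                frac_obs = (obs_nes_values <= nes).mean() / max((obs_nes_values < 0).mean(), 1e-12)
            fdr = min(1.0, frac_null / max(frac_obs, 1e-12))
        results.append(GseaResult(name, es_obs[name], nes, p_perm_by_set[name], fdr, len(genes)))

    if fdr_method == "bh":
        ps = np.array([r.p_perm for r in results])
        order = np.argsort(ps)
        m = len(ps)
        adj = np.empty(m)
        running = 1.0
        for rank_i, idx in enumerate(order[::-1]):
            i = m - rank_i  # position from the largest p
            running = min(running, ps[idx] * m / i)
            adj[idx] = running
        for r, q in zip(results, adj):
            r.fdr = float(q)
    return results


def classify_targets(
    results: list[GseaResult], fdr_cut: float = 0.05
) -> tuple[list[str], list[str]]:
    """Split significant sets by enrichment direction.

    Returns (sets enriched toward the positive/A end, toward the
    negative/B end); sets at or above the FDR cutoff are unreported.
    """
    toward_a = [r.set_name for r in results if r.fdr < fdr_cut and r.nes > 0]
    toward_b = [r.set_name for r in results if r.fdr < fdr_cut and r.nes < 0]
    return toward_a, toward_b


def results_frame(results: list[GseaResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "set": r.set_name,
                "size": r.size,
                "ES": r.es,
                "NES": r.nes,
                "p_perm": r.p_perm,
                "fdr": r.fdr,
                "direction": r.direction,
            }
            for r in results
        ]
    )
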