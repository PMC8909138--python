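"""Signature-matrix bulk deconvolution (digital cytometry).

A signature matrix of population-specific marker genes is built from the
single-cell groups (one-vs-rest moderated t), and bulk samples are scored
by non-negative least squares against the mean population profiles.  The
scores are "absolute": raw non-negative regression coefficients carrying
the scale of the bulk sample, never renormalized to sum to one.  Fit
significance per sample comes from gene-label permutations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .io import ExpressionMatrix, UNIT_TPM, ValidationError, log2_tpm1
from .groups import CellGroup
from .diffexp import moderated_t

logger = logging.getLogger(__name__)


@dataclass
class SignatureMatrix:
    """Mean TPM profiles of marker genes per population."""

    genes: list[str]
    populations: list[str]
    profiles: np.ndarray  # genes x populations

    def __post_init__(self) -> None:
        self.profiles = np.asarray(self.profiles, dtype=float)
        if len(self.populations) < 2:
            raise ValidationError("signature needs >= 2 populations")
        if self.profiles.shape != (len(self.genes), len(self.populations)):
            raise ValidationError("profile shape does not match genes x populations")
        if not np.isfinite(np.linalg.cond(self.profiles)):
            raise ValidationError("signature matrix is singular")

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.profiles, index=self.genes, columns=self.populations).to_csv(
            path, sep="\t", index_label="gene"
        )


@dataclass
class DeconvResult:
    """Per-sample absolute population scores with fit diagnostics."""

    samples: list[str]
    populations: list[str]
    scores: np.ndarray  # samples x populations, >= 0
    rmse: np.ndarray
    p_perm: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.scores, index=self.samples, columns=self.populations)
        df["rmse"] = self.rmse
        df["p_perm"] = self.p_perm
        return df

    def population_scores(self, pop: str) -> pd.Series:
        return pd.Series(self.scores[:, self.populations.index(pop)], index=self.samples, name=pop)


def build_signature(
    m: ExpressionMatrix,
    groups: list[CellGroup],
    q_cut: float = 0.01,
    max_genes_per_pop: int = 200,
) -> SignatureMatrix:
    """Select population-specific marker genes and average their profiles.

    Per population, genes over-expressed versus all other populations
    (one-vs-rest moderated t on log2(TPM+1), Bonferroni-adjusted p < q_cut,
    positive log fold change) are ranked by t and capped at
    ``max_genes_per_pop``.  Profiles are mean TPM over each population's
    cells across the union of selected genes.
    """
    if m.unit != UNIT_TPM:
        raise ValidationError(f"build_signature expects TPM input, got {m.unit}")
    all_members = [c for g in groups for c in g.cell_ids]
    if len(set(all_members)) != len(all_members):
        raise ValidationError("groups must be disjoint to build a signature")
    logm = log2_tpm1(m)
    selected: dict[str, list[str]] = {}
    for g in groups:
        rest = [c for other in groups for c in other.cell_ids if other.name != g.name]
        deg = moderated_t(logm, g.cell_ids, rest)
        tab = deg.table
        hits = tab[(tab["p_adj"] < q_cut) & (tab["logFC"] > 0) & ~tab["zero_variance"]]
        hits = hits.sort_values(["t", "gene"], ascending=[False, True])
        selected[g.name] = hits["gene"].head(max_genes_per_pop).tolist()
        if not selected[g.name]:
            logger.warning("no marker genes for population %r at q < %g", g.name, q_cut)
    union = sorted(set(gene for genes in selected.values() for gene in genes))
    if not union:
        raise ValidationError(
            f"no gene differential between populations at q < {q_cut}; relax q_cut"
        )
    sub = m.subset_genes(union)
    profiles = np.column_stack(
        [sub.values[:, sub.cell_indices(g.cell_ids)].mean(axis=1) for g in groups]
    )
    return SignatureMatrix(union, [g.name for g in groups], profiles)


def deconvolve(
    sig: SignatureMatrix,
    bulk: ExpressionMatrix,
    n_perm: int = 100,
    seed: int | np.random.Generator = 0,
) -> DeconvResult:
    """Absolute-mode population scores for each bulk sample by NNLS.

    The bulk sub-vector over the signature genes is regressed on the
    population profiles with non-negativity constraints; the raw
    coefficients are the absolute scores.  ``p_perm`` is the fraction (with
    +1 smoothing) of ``n_perm`` gene-label permutations of the bulk vector
    whose refit achieves a fitted-vs-observed correlation at least as high
    as the real fit.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    present = [g for g in sig.genes if bulk.has_gene(g)]
    missing = sorted(set(sig.genes) - set(present))
    if len(present) < 0.5 * len(sig.genes):
        raise ValidationError(
            f"only {len(present)}/{len(sig.genes)} signature genes present in bulk"
        )
    if len(present) < len(sig.populations):
        raise ValidationError("fewer shared genes than populations; cannot deconvolve")
    if missing:
        logger.warning("signature genes missing from bulk: %s", missing[:10])
    a = sig.profiles[[sig.genes.index(g) for g in present]]
    sub = bulk.subset_genes(present)

    n_samples = sub.n_cells
    scores = np.zeros((n_samples, len(sig.populations)))
    rmse = np.zeros(n_samples)
    p_perm = np.ones(n_samples)
    for j in range(n_samples):
        y = sub.values[:, j]
        coef, resid = nnls(a, y)
        scores[j] = coef
        rmse[j] = resid / np.sqrt(len(y))
        fitted = a @ coef
        real_r = _safe_corr(fitted, y)
        hits = 0
        for _ in range(n_perm):
            yp = rng.permutation(y)
            cp, _ = nnls(a, yp)
            if _safe_corr(a @ cp, yp) >= real_r:
                hits += 1
        p_perm[j] = (hits + 1) / (n_perm + 1)
    return DeconvResult(list(sub.cell_ids), list(sig.populations), scores, rmse, p_perm)


def _safe_corr(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def stratify_by_score(scores: pd.Series, rule: str = "mean") -> pd.Series:
    """Label samples high/low around the mean (or median) score.

    Ties with the cutoff go to "low": high means strictly above.
    """
    if len(scores) < 2:
        raise ValidationError("need >= 2 samples to stratify")
    if scores.nunique() == 1:
        raise ValidationError("constant scores; stratification is degenerate")
    if rule == "mean":
        cutoff = float(scores.mean())
    elif rule == "median":
        cutoff = float(scores.median())
    else:
        raise ValidationError(f"unknown rule {rule!r}; use 'mean' or 'median'")
    return pd.Series(np.where(scores.to_numpy() > cutoff, "high", "low"), index=scores.index, name="stratum")
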