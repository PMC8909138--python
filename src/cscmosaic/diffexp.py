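"""Differential expression and downstream structure.

The core test is an empirical-Bayes moderated t: per-gene pooled variances
are shrunk toward a prior (d0, s0^2) estimated by method of moments on the
log sample variances, which stabilizes inference in the small private-cell
cohorts (17-22 cells).  Companions: Bonferroni DEG filtering at p < 0.005
and |log2 FC| > 2, variable-gene selection, 3-D PCA, hierarchical
clustering, row z-scoring and pairwise Wilcoxon score comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import pdist
from scipy.special import digamma, polygamma
from scipy.stats import mannwhitneyu
from scipy import stats

from .io import ExpressionMatrix, UNIT_LOG2_TPM1, UNIT_ZSCORE, ValidationError
from .groups import CellGroup
from .scoring import CellScores

logger = logging.getLogger(__name__)

_D0_CAP = 1e6  # represents "infinite" shrinkage


def _trigamma(x: np.ndarray | float) -> np.ndarray | float:
    return polygamma(1, x)


def _trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return _D0_CAP
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = float(polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(polygamma(2, x))
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


@dataclass
class DegTable:
    """Per-gene moderated-t results with Bonferroni adjustment."""

    table: pd.DataFrame  # gene, logFC, t, p, p_adj, significant, zero_variance
    d0: float
    s0_sq: float
    n_a: int
    n_b: int

    def significant_genes(self) -> list[str]:
        return self.table.loc[self.table["significant"], "gene"].tolist()

    def ranking(self) -> pd.Series:
        """Signed gene ranking (moderated t) for enrichment analysis."""
        s = pd.Series(self.table["t"].to_numpy(), index=self.table["gene"].to_numpy())
        return s.dropna()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def moderated_t(m: ExpressionMatrix, cells_a: Iterable[str], cells_b: Iterable[str]) -> DegTable:
    """Empirical-Bayes moderated t-test between two disjoint cell cohorts.

    Works on log2(TPM+1).  Per gene: logFC = mean(A) - mean(B); the pooled
    residual variance s2_g (df d = |A|+|B|-2) is shrunk to the posterior
    (d0*s0^2 + d*s2_g)/(d0 + d) with the prior fit by method of moments on
    log s2_g (trigamma inversion); t is referred to a t distribution with
    d0 + d degrees of freedom.  Genes with zero variance in both cohorts
    have no defined t and are reported with p = 1 and a flag.
    """
    if m.unit != UNIT_LOG2_TPM1:
        raise ValidationError(f"moderated_t expects LOG2_TPM1 input, got {m.unit}")
    a = sorted(set(cells_a))
    b = sorted(set(cells_b))
    if set(a) & set(b):
        raise ValidationError("cohorts must be disjoint")
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each cohort needs >= 2 cells")
    xa = m.values[:, m.cell_indices(a)]
    xb = m.values[:, m.cell_indices(b)]
    na, nb = len(a), len(b)
    d = na + nb - 2
    if d <= 0:
        raise ValidationError("zero residual degrees of freedom")

    mean_a = xa.mean(axis=1)
    mean_b = xb.mean(axis=1)
    logfc = mean_a - mean_b
    ss = ((xa - mean_a[:, None]) ** 2).sum(axis=1) + ((xb - mean_b[:, None]) ** 2).sum(axis=1)
    s2 = ss / d
    zero_var = s2 <= 0

    # prior by method of moments on log sample variances (positive ones)
    s2_pos = s2[~zero_var]
    if s2_pos.size == 0:
        raise ValidationError("every gene has zero variance in both cohorts")
    z = np.log(s2_pos)
    e = z - digamma(d / 2.0) + np.log(d / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1)) - float(_trigamma(d / 2.0)) if e.size > 1 else 0.0
    if e_var > 0:
        d0 = min(2.0 * _trigamma_inverse(e_var), _D0_CAP)
        s0_sq = float(np.exp(e_mean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        # no excess spread in the log variances: infinite shrinkage toward
        # the geometric-mean variance, so t collapses to the ordinary
        # pooled-variance t when all genes agree
        d0 = _D0_CAP
        s0_sq = float(np.exp(np.mean(z)))

    s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    df_total = min(d0 + d, _D0_CAP)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(zero_var, np.nan, logfc / se)
    p = np.where(zero_var, 1.0, 2.0 * stats.t.sf(np.abs(np.where(zero_var, 0.0, t)), df_total))
    n_genes = m.n_genes
    p_adj = np.minimum(1.0, p * n_genes)

    table = pd.DataFrame(
        {
            "gene": m.gene_ids,
            "logFC": logfc,
            "t": t,
            "p": p,
            "p_adj": p_adj,
            "significant": False,
            "zero_variance": zero_var,
        }
    )
    return DegTable(table, d0, s0_sq, na, nb)


def deg_filter(t: DegTable, alpha: float = 0.005, lfc_cut: float = 2.0) -> DegTable:
    """Set the significance flag: adjusted p < alpha and |log2 FC| > lfc_cut."""
    tab = t.table.copy()
    tab["significant"] = (tab["p_adj"] < alpha) & (tab["logFC"].abs() > lfc_cut)
    return DegTable(tab, t.d0, t.s0_sq, t.n_a, t.n_b)


def top_variable_genes(m: ExpressionMatrix, n: int = 1000) -> list[str]:
    """The n genes with the highest expression variance across cells."""
    if n > m.n_genes:
        raise ValidationError(f"requested {n} genes, matrix has {m.n_genes}")
    var = m.values.var(axis=1, ddof=1)
    order = sorted(range(m.n_genes), key=lambda i: (-var[i], m.gene_ids[i]))
    return [m.gene_ids[i] for i in order[:n]]


def pca_embed(
    m: ExpressionMatrix, genes: Sequence[str], k: int = 3, scale: bool = False
) -> pd.DataFrame:
    """Project cells onto the top-k principal components of the gene subset.

    Genes are centered (and optionally unit-scaled); the sign of each
    component is fixed so its largest-magnitude gene loading is positive.
    Returns a cells x k coordinate frame (columns PC1..PCk).
    """
    missing = [g for g in genes if not m.has_gene(g)]
    if missing:
        raise ValidationError(f"genes absent from matrix: {missing[:5]}")
    sub = m.subset_genes(list(genes))
    x = sub.values.T.astype(float)  # cells x genes
    x = x - x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        x = x / sd
    max_k = min(x.shape)
    if k > max_k:
        raise ValidationError(f"k={k} exceeds matrix rank bound {max_k}")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    for i in range(k):
        j = int(np.argmax(np.abs(vt[i])))
        if vt[i, j] < 0:
            vt[i] *= -1.0
            u[:, i] *= -1.0
    coords = u[:, :k] * s[:k]
    return pd.DataFrame(coords, index=m.cell_ids, columns=[f"PC{i+1}" for i in range(k)])


def zscore_rows(m: ExpressionMatrix) -> ExpressionMatrix:
    """Standardize each gene across cells: (x - mean) / sd (sample sd).

    Constant rows become all zeros with a warning.
    """
    mean = m.values.mean(axis=1, keepdims=True)
    sd = m.values.std(axis=1, ddof=1, keepdims=True)
    const = sd[:, 0] == 0
    if const.any():
        logger.warning("%d constant gene(s) z-scored to zeros", int(const.sum()))
    sd[sd == 0] = 1.0
    return ExpressionMatrix((m.values - mean) / sd, list(m.gene_ids), list(m.cell_ids), UNIT_ZSCORE)


@dataclass
class ClusterTree:
    """Agglomerative merge history over labelled items."""

    linkage: np.ndarray  # scipy linkage matrix
    labels: list[str]

    def __post_init__(self) -> None:
        heights = self.linkage[:, 2]
        if np.any(np.diff(heights) < -1e-12):
            raise ValidationError("merge heights must be non-decreasing")

    @property
    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in sch.leaves_list(self.linkage)]

    def to_newick(self) -> str:
        tree = sch.to_tree(self.linkage)

        def rec(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            return f"({rec(node.left)},{rec(node.right)}):{node.dist:.6g}"

        return rec(tree) + ";"


def hcluster(
    data: np.ndarray | pd.DataFrame,
    linkage: str = "average",
    metric: str = "euclidean",
    labels: Sequence[str] | None = None,
) -> ClusterTree:
    """Hierarchical agglomerative clustering of the rows of ``data``."""
    if linkage not in ("average", "complete"):
        raise ValidationError(f"unsupported linkage {linkage!r}")
    if metric not in ("euclidean", "correlation"):
        raise ValidationError(f"unsupported metric {metric!r}")
    if isinstance(data, pd.DataFrame):
        if labels is None:
            labels = [str(i) for i in data.index]
        data = data.to_numpy(dtype=float)
    data = np.asarray(data, dtype=float)
    if data.shape[0] < 2:
        raise ValidationError("need >= 2 items to cluster")
    if labels is None:
        labels = [str(i) for i in range(data.shape[0])]
    dists = pdist(data, metric=metric)
    if not np.isfinite(dists).all():
        raise ValidationError("non-finite pairwise distances")
    z = sch.linkage(dists, method=linkage)
    return ClusterTree(z, list(labels))


def wilcoxon_pairwise(
    scores: CellScores,
    groups: list[CellGroup],
    reference: str,
    exact: bool = False,
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum test of the reference group's scores
    against each other group, Bonferroni-adjusted over the comparisons.

    Cells shared with the reference are removed from the comparator so the
    two samples are independent.  The normal approximation with tie and
    continuity correction is used; ``exact=True`` switches to exact
    enumeration for samples of <= 10.
    """
    names = [g.name for g in groups]
    if reference not in names:
        raise ValidationError(f"reference {reference!r} not among groups {names}")
    series = scores.as_series()
    ref_group = next(g for g in groups if g.name == reference)
    ref_vals = series.loc[list(ref_group.cell_ids)].to_numpy()
    rows = []
    others = [g for g in groups if g.name != reference]
    for g in others:
        cells = [c for c in g.cell_ids if c not in ref_group.members]
        if len(cells) < 3 or len(ref_vals) < 3:
            raise ValidationError(f"group {g.name!r} too small (< 3 cells) for rank-sum test")
        vals = series.loc[cells].to_numpy()
        method = "exact" if exact and max(len(ref_vals), len(vals)) <= 10 else "asymptotic"
        res = mannwhitneyu(ref_vals, vals, alternative="two-sided", method=method)
        n_ref = len(ref_vals)
        w = float(res.statistic) + n_ref * (n_ref + 1) / 2.0  # rank-sum of reference
        rows.append({"group": g.name, "W": w, "p": float(res.pvalue)})
    out = pd.DataFrame(rows)
    out["p_adj"] = np.minimum(1.0, out["p"] * len(others))
    return out
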