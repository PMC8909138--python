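"""Moderated-t DEG, variable genes, PCA, clustering, z-scores, Wilcoxon."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import digamma, polygamma
from scipy import stats

import cscmosaic as cm
from cscmosaic.io import ValidationError


def _log_matrix(values, genes=None, cells=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    cells = cells or [f"c{i}" for i in range(values.shape[1])]
    return cm.ExpressionMatrix(values, genes, cells, unit="LOG2_TPM1")


def reference_moderated_t(xa, xb):
    """Straight-line re-derivation of the moderated t for the oracle:
    pooled variances, method-of-moments prior on log variances (scalar
    Newton trigamma inversion), posterior shrinkage, t and p."""
    na, nb = xa.shape[1], xb.shape[1]
    d = na + nb - 2
    logfc = xa.mean(1) - xb.mean(1)
    ss = ((xa - xa.mean(1, keepdims=True)) ** 2).sum(1) + ((xb - xb.mean(1, keepdims=True)) ** 2).sum(1)
    s2 = ss / d
    e = np.log(s2) - digamma(d / 2) + np.log(d / 2)
    evar = e.var(ddof=1) - polygamma(1, d / 2)
    if evar > 0:
        x = 0.5 + 1.0 / evar
        for _ in range(100):
            tri = polygamma(1, x)
            step = tri * (1 - tri / evar) / polygamma(2, x)
            x += step
            if abs(step) < 1e-10 * x:
                break
        d0 = 2 * x
        s0 = np.exp(e.mean() + digamma(d0 / 2) - np.log(d0 / 2))
    else:
        d0, s0 = 1e6, np.exp(e.mean())
    s2p = (d0 * s0 + d * s2) / (d0 + d)
    t = logfc / np.sqrt(s2p * (1 / na + 1 / nb))
    p = 2 * stats.t.sf(np.abs(t), min(d0 + d, 1e6))
    return logfc, t, p


class TestModeratedT:
    def test_three_gene_toy_matches_direct_arithmetic(self):
        """4 vs 4 cells, 3 genes with hand-set means/variances: logFC, t and
        p reproduce the formulas evaluated independently."""
        xa = np.array([[5.0, 6.0, 5.5, 6.5], [1.0, 1.2, 0.8, 1.0], [3.0, 3.1, 2.9, 3.0]])
        xb = np.array([[2.0, 2.5, 1.5, 2.0], [1.1, 0.9, 1.0, 1.0], [6.0, 5.0, 5.5, 5.5]])
        m = _log_matrix(np.hstack([xa, xb]), cells=[f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)])
        deg = cm.moderated_t(m, [f"a{i}" for i in range(4)], [f"b{i}" for i in range(4)])
        logfc, t, p = reference_moderated_t(xa, xb)
        np.testing.assert_allclose(deg.table["logFC"], logfc)
        np.testing.assert_allclose(deg.table["t"], t, rtol=1e-8)
        np.testing.assert_allclose(deg.table["p"], p, rtol=1e-8)

    def test_swapping_cohorts_negates_logfc_and_t(self):
        rng = np.random.default_rng(2)
        m = _log_matrix(rng.normal(3, 1, size=(40, 12)))
        a, b = m.cell_ids[:6], m.cell_ids[6:]
        fwd = cm.moderated_t(m, a, b).table
        rev = cm.moderated_t(m, b, a).table
        np.testing.assert_allclose(fwd["logFC"], -rev["logFC"])
        np.testing.assert_allclose(fwd["t"], -rev["t"])
        np.testing.assert_allclose(fwd["p"], rev["p"])

    def test_identical_variances_collapse_to_ordinary_t(self):
        """When every gene shares the same sample variance the prior has
        nothing to add: t_mod equals the ordinary pooled-variance t."""
        rng = np.random.default_rng(3)
        pattern = rng.normal(size=10)  # same residuals for every gene
        mu = rng.uniform(1, 5, size=25)
        vals = mu[:, None] + pattern[None, :]
        vals[:, :5] += rng.uniform(0, 2, size=25)[:, None]  # group shift
        m = _log_matrix(vals)
        a, b = m.cell_ids[:5], m.cell_ids[5:]
        deg = cm.moderated_t(m, a, b)
        xa, xb = vals[:, :5], vals[:, 5:]
        d = 8
        s2 = (((xa - xa.mean(1, keepdims=True)) ** 2).sum(1) + ((xb - xb.mean(1, keepdims=True)) ** 2).sum(1)) / d
        t_ord = (xa.mean(1) - xb.mean(1)) / np.sqrt(s2 * (1 / 5 + 1 / 5))
        np.testing.assert_allclose(deg.table["t"], t_ord, rtol=1e-6)

    def test_zero_variance_gene_flagged_with_p_one(self):
        vals = np.vstack([np.r_[np.full(4, 2.0), np.full(4, 5.0)],
                          np.random.default_rng(0).normal(size=(5, 8))])
        m = _log_matrix(vals)
        deg = cm.moderated_t(m, m.cell_ids[:4], m.cell_ids[4:])
        row = deg.table.iloc[0]
        assert row["zero_variance"]
        assert row["p"] == 1.0
        assert np.isnan(row["t"])

    def test_overlapping_cohorts_rejected(self, small_matrix):
        logm = cm.log2_tpm1(small_matrix)
        with pytest.raises(ValidationError, match="disjoint"):
            cm.moderated_t(logm, logm.cell_ids[:4], logm.cell_ids[3:8])

    def test_bonferroni_never_below_p_and_monotone(self):
        rng = np.random.default_rng(4)
        m = _log_matrix(rng.normal(size=(60, 10)))
        deg = cm.moderated_t(m, m.cell_ids[:5], m.cell_ids[5:]).table
        assert (deg["p_adj"] >= deg["p"] - 1e-15).all()
        order = deg.sort_values("p")
        assert order["p_adj"].is_monotonic_increasing


class TestDegFilter:
    @pytest.mark.parametrize(
        "p_adj,logfc,expect",
        [(0.004, 2.5, True), (0.004, 1.0, False), (0.006, 3.0, False)],
    )
    def test_joint_cutoff(self, p_adj, logfc, expect):
        tab = pd.DataFrame(
            {"gene": ["g"], "logFC": [logfc], "t": [1.0], "p": [p_adj / 10],
             "p_adj": [p_adj], "significant": [False], "zero_variance": [False]}
        )
        deg = cm.deg_filter(cm.DegTable(tab, 5.0, 1.0, 4, 4))
        assert bool(deg.table["significant"].iloc[0]) is expect


class TestTopVariableGenes:
    def test_matches_brute_force_sort(self):
        rng = np.random.default_rng(6)
        vals = rng.lognormal(0, 1, size=(20, 15))
        m = _log_matrix(vals)
        got = cm.top_variable_genes(m, 20)
        var = [float(np.var(vals[i], ddof=1)) for i in range(20)]
        expect = [g for _, g in sorted(zip(var, m.gene_ids), key=lambda vg: (-vg[0], vg[1]))]
        assert got == expect

    def test_planted_high_variance_gene_first(self, small_matrix):
        vals = small_matrix.values.copy()
        vals[7] = np.linspace(0, 1000, small_matrix.n_cells)
        m = _log_matrix(vals, genes=small_matrix.gene_ids, cells=small_matrix.cell_ids)
        assert cm.top_variable_genes(m, 5)[0] == "g07"

    def test_n_larger_than_gene_count_is_error(self, small_matrix):
        with pytest.raises(ValidationError):
            cm.top_variable_genes(small_matrix, small_matrix.n_genes + 1)


class TestPcaEmbed:
    def test_separates_planted_clusters(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(0, 1, size=(30, 40))
        vals[:, 20:] += 10.0  # second cluster shifted on every gene
        m = _log_matrix(vals)
        coords = cm.pca_embed(m, m.gene_ids, k=3)
        pc1 = coords["PC1"].to_numpy()
        a, b = pc1[:20], pc1[20:]
        between = abs(a.mean() - b.mean())
        within = max(a.std(), b.std())
        assert between / within > 5

    def test_duplicated_cell_gets_identical_coordinates(self, small_matrix):
        m = small_matrix
        dup = cm.ExpressionMatrix(
            np.column_stack([m.values, m.values[:, 0]]), m.gene_ids, m.cell_ids + ["dup"]
        )
        logm = cm.log2_tpm1(dup)
        coords = cm.pca_embed(logm, logm.gene_ids, k=3)
        np.testing.assert_allclose(coords.loc["dup"], coords.iloc[0], atol=1e-8)

    def test_full_rank_conserves_total_variance(self):
        rng = np.random.default_rng(9)
        vals = rng.normal(size=(6, 9))
        m = _log_matrix(vals)
        k = 6
        coords = cm.pca_embed(m, m.gene_ids, k=k)
        centered = vals.T - vals.T.mean(0)
        assert np.sum(coords.to_numpy() ** 2) == pytest.approx(np.sum(centered**2))

    def test_k_too_large_is_error(self, small_matrix):
        logm = cm.log2_tpm1(small_matrix)
        with pytest.raises(ValidationError):
            cm.pca_embed(logm, logm.gene_ids, k=100)

    def test_cell_order_invariance_up_to_sign(self, small_matrix):
        logm = cm.log2_tpm1(small_matrix)
        fwd = cm.pca_embed(logm, logm.gene_ids, k=2)
        shuffled = logm.subset_cells(list(reversed(logm.cell_ids)))
        rev = cm.pca_embed(shuffled, logm.gene_ids, k=2)
        np.testing.assert_allclose(
            np.abs(fwd.loc[logm.cell_ids].to_numpy()),
            np.abs(rev.loc[logm.cell_ids].to_numpy()),
            atol=1e-8,
        )


class TestZscoreRows:
    def test_known_row(self):
        m = _log_matrix([[1.0, 2.0, 3.0]])
        z = cm.zscore_rows(m)
        np.testing.assert_allclose(z.values[0], [-1.0, 0.0, 1.0])
        assert z.unit == "ZSCORE"

    def test_constant_row_becomes_zeros_with_warning(self, caplog):
        m = _log_matrix([[4.0, 4.0, 4.0], [1.0, 2.0, 3.0]])
        with caplog.at_level("WARNING"):
            z = cm.zscore_rows(m)
        np.testing.assert_allclose(z.values[0], 0.0)
        assert "constant" in caplog.text

    def test_idempotent_on_nonconstant_rows(self, small_matrix):
        z = cm.zscore_rows(small_matrix)
        zz = cm.zscore_rows(z)
        np.testing.assert_allclose(zz.values, z.values, atol=1e-12)

    def test_rows_standardized(self, small_matrix):
        z = cm.zscore_rows(small_matrix)
        np.testing.assert_allclose(z.values.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.values.std(axis=1, ddof=1), 1.0, atol=1e-12)


def brute_force_average_linkage(points):
    """Naive agglomeration: repeatedly merge the closest pair of clusters
    under average linkage, recording the merge order."""
    clusters = {i: [i] for i in range(len(points))}
    merges = []
    next_id = len(points)
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                d = np.mean(
                    [np.linalg.norm(points[i] - points[j]) for i in clusters[a] for j in clusters[b]]
                )
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        merges.append((frozenset(clusters[a]) | frozenset(clusters[b]), d))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return merges


class TestHcluster:
    def test_close_pair_merges_first(self):
        pts = np.array([[0.0], [1.0], [10.0]])
        tree = cm.hcluster(pts, labels=["a", "b", "c"])
        assert set(tree.linkage[0, :2].astype(int)) == {0, 1}

    def test_six_item_toy_matches_brute_force(self):
        rng = np.random.default_rng(10)
        pts = rng.normal(size=(6, 3))
        tree = cm.hcluster(pts, linkage="average")
        expect = brute_force_average_linkage(pts)
        # reconstruct merged leaf sets from the scipy linkage matrix
        sets = {i: frozenset([i]) for i in range(6)}
        for row_i, row in enumerate(tree.linkage):
            merged = sets[int(row[0])] | sets[int(row[1])]
            sets[6 + row_i] = merged
            assert merged == expect[row_i][0]
            assert row[2] == pytest.approx(expect[row_i][1])

    def test_duplicated_item_merges_at_height_zero(self):
        pts = np.array([[1.0, 1.0], [1.0, 1.0], [5.0, 5.0]])
        tree = cm.hcluster(pts)
        assert tree.linkage[0, 2] == pytest.approx(0.0)
        assert set(tree.linkage[0, :2].astype(int)) == {0, 1}

    def test_newick_export_contains_all_labels(self):
        pts = np.random.default_rng(11).normal(size=(4, 2))
        tree = cm.hcluster(pts, labels=["w", "x", "y", "z"])
        nwk = tree.to_newick()
        assert nwk.endswith(";") and all(l in nwk for l in "wxyz")

    def test_nonfinite_distance_is_error(self):
        pts = np.array([[0.0, 0.0], [0.0, 0.0]])
        with pytest.raises(ValidationError):
            cm.hcluster(pts, metric="correlation")  # zero-variance rows


class TestWilcoxonPairwise:
    def _setup(self, ref_vals, other_vals):
        ids = [f"r{i}" for i in range(len(ref_vals))] + [f"o{i}" for i in range(len(other_vals))]
        scores = cm.CellScores("s", ids, np.r_[ref_vals, other_vals])
        ref = cm.CellGroup("REF", ids[: len(ref_vals)], np.ones(len(ref_vals)), {"kind": "signature"})
        oth = cm.CellGroup("OTH", ids[len(ref_vals):], np.ones(len(other_vals)), {"kind": "marker"})
        return scores, [ref, oth]

    def test_identical_distributions_give_large_p(self):
        vals = np.arange(10.0)
        scores, groups = self._setup(vals, vals + 0.0)
        out = cm.wilcoxon_pairwise(scores, groups, "REF")
        assert out["p"].iloc[0] > 0.9

    def test_complete_separation_gives_minimal_p(self):
        scores, groups = self._setup(np.arange(10, 20.0), np.arange(0, 10.0))
        out = cm.wilcoxon_pairwise(scores, groups, "REF", exact=True)
        # smallest attainable two-sided exact p for 10 vs 10
        assert out["p"].iloc[0] == pytest.approx(2 / 184756, rel=1e-6)

    def test_w_matches_exhaustive_rank_sums(self):
        """5 vs 5 toy: W equals the rank-sum of the reference sample
        computed by direct ranking."""
        ref = np.array([3.1, 0.2, 7.7, 5.5, 1.1])
        oth = np.array([2.2, 8.8, 4.4, 6.6, 0.5])
        scores, groups = self._setup(ref, oth)
        out = cm.wilcoxon_pairwise(scores, groups, "REF", exact=True)
        pooled = np.r_[ref, oth]
        ranks = stats.rankdata(pooled)
        assert out["W"].iloc[0] == pytest.approx(ranks[:5].sum())

    def test_small_group_is_error(self):
        scores, groups = self._setup(np.arange(5.0), np.array([1.0, 2.0]))
        with pytest.raises(ValidationError, match="too small"):
            cm.wilcoxon_pairwise(scores, groups, "REF")

    def test_unknown_reference_is_error(self):
        scores, groups = self._setup(np.arange(5.0), np.arange(5.0))
        with pytest.raises(ValidationError, match="not among"):
            cm.wilcoxon_pairwise(scores, groups, "NOPE")

    def test_bonferroni_over_comparisons(self):
        rng = np.random.default_rng(12)
        ids = [f"c{i}" for i in range(30)]
        scores = cm.CellScores("s", ids, rng.normal(size=30))
        groups = [
            cm.CellGroup("REF", ids[:10], np.ones(10), {}),
            cm.CellGroup("A", ids[10:20], np.ones(10), {}),
            cm.CellGroup("B", ids[20:], np.ones(10), {}),
        ]
        out = cm.wilcoxon_pairwise(scores, groups, "REF")
        np.testing.assert_allclose(out["p_adj"], np.minimum(1.0, out["p"] * 2))
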