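"""Preprocessing ladder: filters, normalization, HVG, MAD, set scoring."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st

from scregkit import qc
from scregkit.qc import HVGParams, QCThresholds


def _adata(counts, genes=None, barcodes=None, mito=None):
    counts = np.asarray(counts)
    n, g = counts.shape
    genes = genes or [f"g{i}" for i in range(g)]
    var = pd.DataFrame(index=pd.Index(genes, name="gene"))
    if mito is not None:
        var["is_mito"] = mito
    return ad.AnnData(
        X=sp.csr_matrix(counts),
        obs=pd.DataFrame(index=barcodes or [f"c{i}" for i in range(n)]),
        var=var)


class TestFilterCellsGenes:
    def test_mito_rule_is_strictly_greater_than_ten_percent(self):
        # cell0: 12% mito -> removed; cell1: exactly 10% -> kept
        counts = np.array([[88, 12], [90, 10], [95, 5]])
        adata = _adata(counts, mito=[False, True])
        t = QCThresholds(min_cells_per_gene=1, max_total_umi=10_000,
                         max_genes_per_cell=100)
        out = qc.filter_cells_genes(adata, t)
        assert list(out.obs_names) == ["c1", "c2"]
        assert out.uns["qc_filter_log"]["cells_mito"] == 1

    def test_doublet_bounds_are_inclusive(self):
        # 49,999 UMIs / 2 genes and 0% mito -> kept; 50,000 -> removed
        counts = np.array([[49_998, 1, 0], [49_999, 1, 0], [1, 1, 0]])
        adata = _adata(counts, mito=[False, False, True])
        t = QCThresholds(min_cells_per_gene=1)
        out = qc.filter_cells_genes(adata, t)
        assert list(out.obs_names) == ["c0", "c2"]

        counts = np.ones((3, 7), dtype=int)
        adata = _adata(counts, mito=[True] + [False] * 6)
        adata.X[0, :] = 0  # c0 expresses 0 genes
        t = QCThresholds(max_genes_per_cell=7, min_cells_per_gene=1,
                         max_mito_frac=None)
        out = qc.filter_cells_genes(adata, t)
        assert "c1" not in out.obs_names and "c2" not in out.obs_names

    def test_gene_prevalence_rule_by_enumeration(self):
        counts = np.array([
            [1, 0, 2, 1],
            [1, 0, 3, 0],
            [2, 1, 1, 0],
            [1, 0, 2, 0],
            [3, 0, 1, 0],
        ])  # gene1 seen in 1 cell, gene3 in 1 cell
        adata = _adata(counts)
        t = QCThresholds(max_mito_frac=None, min_cells_per_gene=2)
        out = qc.filter_cells_genes(adata, t)
        assert list(out.var_names) == ["g0", "g2"]
        assert out.uns["qc_filter_log"]["genes_removed"] == 2

    def test_requires_mito_annotation(self):
        adata = _adata(np.ones((3, 3), dtype=int))
        with pytest.raises(ValueError, match="mito"):
            qc.filter_cells_genes(adata, QCThresholds(min_cells_per_gene=1))

    def test_rerun_is_noop_for_cell_rules(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(2.0, size=(50, 30))
        adata = _adata(counts, mito=[True] * 2 + [False] * 28)
        t = QCThresholds(max_mito_frac=0.5, max_total_umi=120,
                         max_genes_per_cell=25, min_cells_per_gene=5)
        once = qc.filter_cells_genes(adata, t)
        twice = qc.filter_cells_genes(once, t)
        assert twice.uns["qc_filter_log"]["cells_removed"] == 0


class TestNormalizeLog:
    def test_known_values(self):
        adata = _adata(np.array([[5, 0, 5]]))
        out = qc.normalize_log(adata, 10_000)
        np.testing.assert_allclose(
            np.asarray(out.X.todense()),
            np.log1p([[5000.0, 0.0, 5000.0]]))

    def test_identical_composition_gives_identical_vectors(self):
        adata = _adata(np.array([[2, 4, 6], [1, 2, 3], [10, 20, 30]]))
        out = np.asarray(qc.normalize_log(adata).X.todense())
        np.testing.assert_allclose(out[0], out[1])
        np.testing.assert_allclose(out[0], out[2])

    def test_zero_total_cell_is_named(self):
        adata = _adata(np.array([[1, 1], [0, 0]]),
                       barcodes=["good", "empty"])
        with pytest.raises(ValueError, match="empty"):
            qc.normalize_log(adata)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_invertible_given_totals(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.poisson(3.0, size=(8, 12)) + (rng.random((8, 12)) < 0.1)
        counts[:, 0] += 1  # no zero-total cells
        adata = _adata(counts.astype(int))
        out = qc.normalize_log(adata, 10_000)
        X = np.asarray(out.X.todense())
        totals = out.obs["norm_total"].to_numpy()
        rec = np.expm1(X) / 10_000 * totals[:, None]
        assert np.abs(rec - counts).max() < 1e-9


class TestSelectHVG:
    @staticmethod
    def _hvg_oracle(X_norm, n_bins, min_mean, max_mean, min_disp):
        """Independent binned-dispersion recomputation."""
        d = np.expm1(X_norm)
        means = d.mean(axis=0)
        var = d.var(axis=0, ddof=1)
        disp = np.where(means > 0, var / np.where(means > 0, means, 1), np.nan)
        edges = np.quantile(means, np.linspace(0, 1, n_bins + 1)[1:-1])
        bins = np.searchsorted(edges, means, side="right")
        z = np.full_like(means, -np.inf)
        for b in np.unique(bins):
            i = np.where(bins == b)[0]
            ok = np.isfinite(disp[i])
            if ok.sum() == 0:
                continue
            mu, sd = disp[i][ok].mean(), (disp[i][ok].std(ddof=1)
                                          if ok.sum() > 1 else 0.0)
            zi = np.zeros(len(i))
            zi[ok] = (disp[i][ok] - mu) / sd if sd > 0 else 0.0
            zi[~ok] = -np.inf
            z[i] = zi
        return (means > min_mean) & (means < max_mean) & (z >= min_disp)

    def test_planted_high_dispersion_genes_win(self):
        rng = np.random.default_rng(1)
        n, g = 300, 200
        lam = np.full(g, 1.0)
        counts = rng.poisson(lam, size=(n, g)).astype(float)
        # 20 planted noisy genes: same mean, inflated variance
        hot = rng.choice(g, 20, replace=False)
        burst = rng.random((n, 20)) < 0.1
        counts[:, hot] = np.where(burst, rng.poisson(10, size=(n, 20)), 0)
        adata = _adata(counts.astype(int))
        norm = qc.normalize_log(adata)
        X = np.asarray(norm.X.todense())
        p = HVGParams(min_mean=0.0, max_mean=1e6, min_disp=0.5)
        got = set(qc.select_hvg(norm, p))
        expect = {f"g{i}" for i in np.where(
            self._hvg_oracle(X, 20, 0.0, 1e6, 0.5))[0]}
        assert got == expect
        n_hot_selected = len({f"g{i}" for i in hot} & got)
        assert n_hot_selected >= 18

    def test_constant_gene_never_selected_and_mean_bounds(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(5.0, size=(100, 50))
        counts[:, 0] = 3  # constant gene
        adata = _adata(counts)
        norm = qc.normalize_log(adata)
        sel = qc.select_hvg(norm, HVGParams(min_mean=0, max_mean=1e6,
                                            min_disp=0.01))
        assert "g0" not in sel
        # a gene with de-logged mean below min_mean=0.0125 is excluded
        d = np.expm1(np.asarray(norm.X.todense()))
        low = np.where(d.mean(axis=0) < 0.0125)[0]
        sel2 = set(qc.select_hvg(norm, HVGParams(min_disp=-np.inf)))
        assert all(f"g{i}" not in sel2 for i in low)

    def test_gene_permutation_invariance(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(2.0, size=(80, 60))
        adata = _adata(counts)
        norm = qc.normalize_log(adata)
        sel = set(qc.select_hvg(norm))
        perm = rng.permutation(60)
        sel_p = set(qc.select_hvg(norm[:, perm].copy()))
        assert sel == sel_p


class TestRegressOut:
    def test_orthogonal_covariate_leaves_gene_unchanged(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        cov = rng.normal(size=100)
        cov -= cov.mean()
        x_orth = x - x.mean()
        x_orth -= (x_orth @ cov) / (cov @ cov) * cov
        X = x_orth[:, None] + 5.0
        out = qc.regress_out(X, pd.DataFrame({"c": cov}))
        np.testing.assert_allclose(out, X, atol=1e-10)

    def test_exact_linear_gene_becomes_constant(self):
        cov = np.linspace(0, 1, 50)
        X = (2.0 + 3.0 * cov)[:, None]
        out = qc.regress_out(X, pd.DataFrame({"c": cov}))
        assert np.ptp(out) < 1e-10

    def test_matches_pseudoinverse_oracle(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(50, 10))
        C = rng.normal(size=(50, 2))
        out = qc.regress_out(X, pd.DataFrame(C, columns=["a", "b"]))
        D = np.column_stack([np.ones(50), C])
        resid = X - D @ np.linalg.pinv(D) @ X
        np.testing.assert_allclose(out, resid + X.mean(axis=0), atol=1e-10)

    def test_collinear_covariate_dropped(self):
        rng = np.random.default_rng(5)
        c = rng.normal(size=30)
        C = pd.DataFrame({"a": c, "b": 2 * c})
        X = rng.normal(size=(30, 3))
        with pytest.warns(UserWarning, match="collinear"):
            qc.regress_out(X, C)


class TestMADFilter:
    def test_hand_computed_cluster(self):
        # metric [1,2,3,4,100]: median 3, MAD 1 -> only 100 flagged (97 > 5)
        m = pd.DataFrame({"umi": [1, 2, 3, 4, 100]})
        keep = qc.mad_outlier_filter(m, ["a"] * 5, mad_cutoff=5)
        assert keep.tolist() == [True, True, True, True, False]

    def test_zero_mad_removes_nothing(self):
        m = pd.DataFrame({"umi": [7, 7, 7, 7, 1000]})
        # MAD = 0 (median 7, |x-7| median 0) -> conservative, keep all
        keep = qc.mad_outlier_filter(m, ["a"] * 5, mad_cutoff=5)
        assert keep.all()

    def test_infinite_cutoff_is_identity(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame({"umi": rng.normal(size=40),
                          "mito": rng.random(40)})
        keep = qc.mad_outlier_filter(m, ["a"] * 20 + ["b"] * 20,
                                     mad_cutoff=np.inf)
        assert keep.all()

    def test_median_cell_never_removed(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            vals = rng.normal(size=21)
            m = pd.DataFrame({"umi": vals})
            keep = qc.mad_outlier_filter(m, ["a"] * 21, mad_cutoff=0.1)
            med_cell = m["umi"].sub(np.median(vals)).abs().idxmin()
            assert keep[med_cell]

    def test_singleton_cluster_kept_with_warning(self):
        m = pd.DataFrame({"umi": [1.0, 100.0, 101.0, 102.0]})
        with pytest.warns(UserWarning, match="single cell"):
            keep = qc.mad_outlier_filter(m, ["solo", "b", "b", "b"],
                                         mad_cutoff=5)
        assert keep.iloc[0]


class TestGeneSetScore:
    def test_uniform_matrix_scores_zero(self):
        adata = _adata(np.full((10, 40), 3))
        norm = qc.normalize_log(adata)
        s = qc.score_gene_set(norm, [f"g{i}" for i in range(40)], seed=0)
        np.testing.assert_allclose(s.to_numpy(), 0.0, atol=1e-12)

    def test_top_expressed_set_scores_positive(self):
        rng = np.random.default_rng(0)
        base = 60.0 - np.arange(60)  # strictly graded expression
        X = base[None, :] + rng.uniform(0, 0.1, size=(30, 60))
        adata = ad.AnnData(X=X,
                           obs=pd.DataFrame(index=[f"c{i}" for i in range(30)]),
                           var=pd.DataFrame(
                               index=[f"g{i}" for i in range(60)]))
        s = qc.score_gene_set(adata, ["g0", "g1", "g2", "g3"], seed=1,
                              n_bins=5, ctrl_size=8)
        assert (s > 0).all()

    def test_translation_equivariance(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(12, 50))
        adata = ad.AnnData(X=X.copy(),
                           obs=pd.DataFrame(index=[f"c{i}" for i in range(12)]),
                           var=pd.DataFrame(index=[f"g{i}" for i in range(50)]))
        s0 = qc.score_gene_set(adata, ["g3", "g7"], seed=3)
        adata2 = adata.copy()
        adata2.X[5, :] += 4.2  # shift one whole cell
        s1 = qc.score_gene_set(adata2, ["g3", "g7"], seed=3)
        assert abs(s1["c5"] - s0["c5"]) < 1e-9
        np.testing.assert_allclose(s0.drop("c5"), s1.drop("c5"), atol=1e-12)

    def test_missing_set_errors(self):
        adata = _adata(np.ones((3, 3), dtype=int))
        norm = qc.normalize_log(adata)
        with pytest.raises(ValueError, match="no gene"):
            qc.score_gene_set(norm, ["absent"])


class TestCellCycle:
    def _graded(self):
        # 3 cells: S-genes high in cell0, G2M-genes high in cell1, none in cell2
        X = np.ones((3, 30))
        X[0, :5] = 10.0   # S set
        X[1, 5:10] = 10.0  # G2M set
        return ad.AnnData(X=X,
                          obs=pd.DataFrame(index=["s", "g2m", "g1"]),
                          var=pd.DataFrame(
                              index=[f"g{i}" for i in range(30)]))

    def test_phase_assignment(self):
        adata = self._graded()
        s_genes = [f"g{i}" for i in range(5)]
        g2m_genes = [f"g{i}" for i in range(5, 10)]
        phase = qc.assign_cell_cycle(adata, s_genes, g2m_genes, seed=0,
                                     n_bins=5, ctrl_size=5)
        assert phase["s"] == "S"
        assert phase["g2m"] == "G2M"
        assert phase["g1"] == "G1"

    def test_tie_goes_to_s(self):
        # identical S/G2M scores, both positive
        X = np.ones((2, 20))
        X[0, :4] = 5.0
        X[0, 4:8] = 5.0
        adata = ad.AnnData(X=X, obs=pd.DataFrame(index=["hot", "flat"]),
                           var=pd.DataFrame(
                               index=[f"g{i}" for i in range(20)]))
        phase = qc.assign_cell_cycle(adata, [f"g{i}" for i in range(4)],
                                     [f"g{i}" for i in range(4, 8)], seed=0,
                                     n_bins=4, ctrl_size=4)
        assert phase["hot"] == "S"

    def test_empty_intersection_errors(self):
        adata = self._graded()
        with pytest.raises(ValueError):
            qc.assign_cell_cycle(adata, ["nope"], ["g1"])
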