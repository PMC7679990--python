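"""Cell/gene quality filtering, normalization, HVG selection and scoring.

The pre-analysis ladder: hard count-based cell rules, gene prevalence
filtering, relative-count log normalization, binned-dispersion HVG
selection, covariate regression, per-cluster MAD outlier removal, and
bin-matched control gene-set scoring used for cell-cycle annotation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp


@dataclass
class QCThresholds:
    """Cell and gene quality rules.

    A cell is removed when its mitochondrial UMI fraction exceeds
    ``max_mito_frac`` (strictly), or its total UMI count or number of
    expressed genes reaches the respective cap (>=, reading the doublet
    rules literally). Genes seen in fewer than ``min_cells_per_gene``
    cells are dropped afterwards.
    """

    max_mito_frac: float | None = 0.10
    max_total_umi: int = 50_000
    max_genes_per_cell: int = 6_000
    min_cells_per_gene: int = 100
    mad_cutoff: float = 5.0
    scale_factor: float = 10_000.0

    def __post_init__(self) -> None:
        if self.max_mito_frac is not None and not 0 < self.max_mito_frac <= 1:
            raise ValueError("max_mito_frac must be in (0, 1]")
        for name in ("max_total_umi", "max_genes_per_cell",
                     "min_cells_per_gene", "mad_cutoff", "scale_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class HVGParams:
    min_mean: float = 0.0125
    max_mean: float = 3.0
    min_disp: float = 0.5
    n_bins: int = 20

    def __post_init__(self) -> None:
        if not self.min_mean < self.max_mean:
            raise ValueError("min_mean must be < max_mean")


def _dense(X) -> np.ndarray:
    return X.toarray() if sp.issparse(X) else np.asarray(X)


def _mito_mask(adata: ad.AnnData, mito_prefix: str = "MT-") -> np.ndarray:
    if "is_mito" in adata.var:
        return adata.var["is_mito"].to_numpy(dtype=bool)
    return np.asarray(adata.var_names.str.startswith(mito_prefix))


def filter_cells_genes(adata: ad.AnnData, t: QCThresholds,
                       mito_prefix: str = "MT-") -> ad.AnnData:
    """Apply the three cell rules, then the gene prevalence rule.

    The removal counts are recorded in ``.uns['qc_filter_log']``.
    """
    X = adata.X
    totals = np.asarray(X.sum(axis=1)).ravel()
    n_genes_per_cell = np.asarray((X > 0).sum(axis=1)).ravel()
    keep = np.ones(adata.n_obs, dtype=bool)
    log: dict[str, int] = {}
    if t.max_mito_frac is not None:
        mito = _mito_mask(adata, mito_prefix)
        if not mito.any():
            raise ValueError(
                "no mitochondrial gene annotation; set max_mito_frac=None "
                "to disable the rule")
        mito_frac = np.asarray(X[:, mito].sum(axis=1)).ravel() / np.maximum(
            totals, 1)
        bad = mito_frac > t.max_mito_frac
        log["cells_mito"] = int(bad.sum())
        keep &= ~bad
    bad = totals >= t.max_total_umi
    log["cells_total_umi"] = int(bad.sum())
    keep &= ~bad
    bad = n_genes_per_cell >= t.max_genes_per_cell
    log["cells_n_genes"] = int(bad.sum())
    keep &= ~bad
    log["cells_removed"] = int((~keep).sum())

    out = adata[keep].copy()
    prevalence = np.asarray((out.X > 0).sum(axis=0)).ravel()
    gene_keep = prevalence >= t.min_cells_per_gene
    log["genes_removed"] = int((~gene_keep).sum())
    out = out[:, gene_keep].copy()
    out.uns["qc_filter_log"] = log
    return out


def normalize_log(adata: ad.AnnData,
                  scale_factor: float = 10_000.0) -> ad.AnnData:
    """log(1 + count / cell total x scale_factor); totals are stored in
    ``.obs['norm_total']`` so the transform is invertible."""
    totals = np.asarray(adata.X.sum(axis=1)).ravel()
    if np.any(totals == 0):
        bad = adata.obs_names[np.where(totals == 0)[0][0]]
        raise ValueError(f"cell {bad!r} has zero total count")
    out = adata.copy()
    if sp.issparse(out.X):
        Xn = sp.csr_matrix(out.X, dtype=np.float64)
        Xn = sp.diags(scale_factor / totals) @ Xn
        out.X = Xn.log1p()
    else:
        out.X = np.log1p(np.asarray(out.X, dtype=np.float64)
                         / totals[:, None] * scale_factor)
    out.obs["norm_total"] = totals
    out.uns["norm_scale_factor"] = float(scale_factor)
    return out


def select_hvg(adata_norm: ad.AnnData, p: HVGParams | None = None) -> list[str]:
    """Highly variable genes by mean bounds and binned normalized dispersion.

    Mean and dispersion (variance/mean) are computed on the de-logged scale;
    dispersions are z-scored (ddof=1) within ``n_bins`` equal-frequency mean
    bins; selected genes satisfy min_mean < mean < max_mean and normalized
    dispersion >= min_disp, returned in input gene order.
    """
    p = p or HVGParams()
    X = np.expm1(_dense(adata_norm.X))
    means = X.mean(axis=0)
    var = X.var(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(means > 0, var / means, np.nan)

    n_bins = p.n_bins
    if adata_norm.n_vars < n_bins:
        warnings.warn("fewer genes than bins; reducing n_bins")
        n_bins = max(1, adata_norm.n_vars)
    # value-based quantile edges: equal genes within value ties share a bin,
    # so the selection is invariant to gene-order permutation
    edges = np.quantile(means, np.linspace(0, 1, n_bins + 1)[1:-1])
    bin_id = np.searchsorted(edges, means, side="right")

    z = np.full(means.shape, -np.inf)
    for b in np.unique(bin_id):
        idx = np.where(bin_id == b)[0]
        d = disp[idx]
        ok = np.isfinite(d)
        if ok.sum() == 0:
            continue
        mu = d[ok].mean()
        sd = d[ok].std(ddof=1) if ok.sum() > 1 else 0.0
        zb = np.zeros(len(idx))
        zb[ok] = (d[ok] - mu) / sd if sd > 0 else 0.0
        zb[~ok] = -np.inf
        z[idx] = zb

    sel = (means > p.min_mean) & (means < p.max_mean) & (z >= p.min_disp)
    return [g for g, s in zip(adata_norm.var_names, sel) if s]


def regress_out(matrix, covariates: pd.DataFrame):
    """Per-gene OLS of expression on covariates (+ intercept); returns
    residuals with the original gene means restored. Collinear covariates
    are dropped with a warning."""
    adata_in = isinstance(matrix, ad.AnnData)
    X = _dense(matrix.X) if adata_in else np.asarray(matrix, dtype=float)
    C = covariates.to_numpy(dtype=float)
    if not np.all(np.isfinite(C)):
        raise ValueError("covariates must be finite")
    D = np.ones((X.shape[0], 1))
    kept_cols = []
    for j in range(C.shape[1]):
        cand = np.column_stack([D, C[:, j]])
        if np.linalg.matrix_rank(cand) > np.linalg.matrix_rank(D):
            D = cand
            kept_cols.append(j)
        else:
            warnings.warn(
                f"covariate {covariates.columns[j]!r} is collinear; dropped")
    beta, *_ = np.linalg.lstsq(D, X, rcond=None)
    resid = X - D @ beta
    out = resid + X.mean(axis=0, keepdims=True)
    if adata_in:
        res = matrix.copy()
        res.X = out
        return res
    return out


def mad_outlier_filter(metrics: pd.DataFrame, clusters,
                       mad_cutoff: float = 5.0) -> pd.Series:
    """Per-cluster, per-metric MAD rule: flag cells with
    |x - median| / MAD > cutoff in either metric; MAD = median(|x - median|)
    without the normality constant. MAD = 0 flags nothing (conservative);
    size-1 clusters are kept unfiltered with a warning. Returns a boolean
    keep mask indexed like ``metrics``.
    """
    clusters = pd.Series(np.asarray(clusters), index=metrics.index)
    if clusters.isna().any():
        raise ValueError("every cell must carry a cluster label")
    keep = pd.Series(True, index=metrics.index)
    for cl, idx in metrics.groupby(clusters, observed=True).groups.items():
        sub = metrics.loc[idx]
        if len(sub) == 1:
            warnings.warn(f"cluster {cl!r} has a single cell; kept unfiltered")
            continue
        for col in metrics.columns:
            x = sub[col].to_numpy(dtype=float)
            med = np.median(x)
            mad = np.median(np.abs(x - med))
            if mad == 0:
                continue
            flagged = np.abs(x - med) / mad > mad_cutoff
            keep.loc[idx[flagged]] = False
    return keep


def score_gene_set(adata_norm: ad.AnnData, gene_set, n_bins: int = 25,
                   ctrl_size: int = 50, seed: int = 0) -> pd.Series:
    """Per-cell score: mean expression of the set genes minus the mean of
    bin-matched control genes (``ctrl_size`` controls per set gene, drawn
    without replacement from the gene's average-expression bin, falling
    back to with-replacement for small bins)."""
    genes = list(adata_norm.var_names)
    gidx = {g: i for i, g in enumerate(genes)}
    set_idx = [gidx[g] for g in gene_set if g in gidx]
    if not set_idx:
        raise ValueError("no gene of the set is present in the matrix")
    X = _dense(adata_norm.X)
    avg = X.mean(axis=0)
    order = np.argsort(avg, kind="stable")
    rank_of = np.empty(len(genes), dtype=int)
    rank_of[order] = np.arange(len(genes))
    n_bins = min(n_bins, len(genes))
    bin_id = rank_of * n_bins // len(genes)

    rng = np.random.default_rng(seed)
    set_mask = np.zeros(len(genes), dtype=bool)
    set_mask[set_idx] = True
    ctrl: list[np.ndarray] = []
    for gi in set_idx:
        members = np.where(bin_id == bin_id[gi])[0]
        cand = members[~set_mask[members]]
        if len(cand) == 0:
            cand = members
        if len(cand) >= ctrl_size:
            ctrl.append(rng.choice(cand, size=ctrl_size, replace=False))
        else:
            ctrl.append(rng.choice(cand, size=ctrl_size, replace=True))
    ctrl_idx = np.concatenate(ctrl)
    score = X[:, set_idx].mean(axis=1) - X[:, ctrl_idx].mean(axis=1)
    return pd.Series(score, index=adata_norm.obs_names, name="score")


def assign_cell_cycle(adata_norm: ad.AnnData, s_genes, g2m_genes,
                      seed: int = 0, n_bins: int = 25,
                      ctrl_size: int = 50) -> pd.Series:
    """Phase per cell: argmax of the S and G2M gene-set scores when that
    maximum is positive, else G1. A tie with positive scores is called S."""
    s_present = [g for g in s_genes if g in adata_norm.var_names]
    g2m_present = [g for g in g2m_genes if g in adata_norm.var_names]
    if not s_present or not g2m_present:
        raise ValueError("gene list does not intersect the matrix")
    s = score_gene_set(adata_norm, s_present, n_bins, ctrl_size, seed)
    g2m = score_gene_set(adata_norm, g2m_present, n_bins, ctrl_size, seed)
    phase = np.where(
        (s <= 0) & (g2m <= 0), "G1", np.where(s >= g2m, "S", "G2M"))
    return pd.Series(phase, index=adata_norm.obs_names, name="phase")
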