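"""Differential-distribution calling between two cell groups.

Genes are assigned to one of three categories: DZ (the groups differ in
the proportion of cells with a zero count, Fisher's exact test on the
zero/nonzero table), DE (the nonzero expression values shift in mean,
Mann-Whitney test) and DM (the nonzero values change modality, judged by
BIC-selected 1- vs 2-component Gaussian mixtures on the log scale with a
permutation test). Depth correction and the zero-variance jitter guard
are applied up front; p-values are Benjamini-Hochberg adjusted and calls
are gated on effect sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.mixture import GaussianMixture
from statsmodels.stats.multitest import multipletests


@dataclass
class DDParams:
    fdr_cutoff: float = 0.05
    min_abs_log2fc: float = 1.0
    min_zp_diff: float = 10.0  # percentage points
    jitter_halfwidth: float = 0.01
    depth_window: tuple[float, float] | None = None
    dm_requires_fc: bool = False  # also gate DM calls on |log2FC|
    merge_tol: float = 1.0       # log-units below which mixture modes merge
    n_perm: int = 100

    def __post_init__(self) -> None:
        if self.fdr_cutoff <= 0 or self.min_abs_log2fc <= 0 \
                or self.min_zp_diff <= 0:
            raise ValueError("cutoffs must be positive")
        if self.jitter_halfwidth <= 0:
            raise ValueError("jitter_halfwidth must be > 0")


def _two_groups(groups, group_a=None, group_b=None):
    groups = np.asarray(groups)
    if group_a is None or group_b is None:
        seen = pd.unique(groups)
        if len(seen) != 2:
            raise ValueError("exactly two groups required")
        group_a, group_b = seen[0], seen[1]
    ma, mb = groups == group_a, groups == group_b
    if ma.sum() < 2 or mb.sum() < 2:
        raise ValueError("both groups need at least 2 cells")
    return ma, mb


def correct_depth(counts: np.ndarray, batch=None) -> np.ndarray:
    """Remove sequencing-depth (and batch) effects per gene.

    A negative-binomial-flavoured GLM (Poisson fit with a moment dispersion
    estimate) of counts on log10 total UMIs plus batch dummies is fit per
    gene; corrected counts are the prediction at the median depth rescaled
    by the Pearson residual, clipped at zero. All-zero genes pass through.
    """
    Y = np.asarray(counts, dtype=float)
    totals = Y.sum(axis=1)
    if np.any(totals <= 0):
        raise ValueError("cells with zero total count cannot be depth-corrected")
    logd = np.log10(totals)
    cols = [np.ones_like(logd)]
    if np.ptp(logd) > 1e-12:
        cols.append(logd)
        depth_col = 1
    else:
        depth_col = None
    if batch is not None:
        b = pd.Categorical(np.asarray(batch))
        for lev in b.categories[1:]:
            cols.append((b == lev).astype(float))
    D = np.column_stack(cols)
    med = np.median(logd)
    x_ref = np.zeros(D.shape[1])
    x_ref[0] = 1.0
    if depth_col is not None:
        x_ref[depth_col] = med

    out = np.zeros_like(Y)
    for g in range(Y.shape[1]):
        y = Y[:, g]
        if not y.any():
            continue
        try:
            fit = sm.GLM(y, D, family=sm.families.Poisson()).fit()
            mu = fit.predict(D)
            mu_ref = float(np.exp(x_ref @ fit.params))
        except Exception:  # pragma: no cover - degenerate gene
            out[:, g] = y
            continue
        alpha = max(0.0, float(np.sum((y - mu) ** 2 - mu) / np.sum(mu ** 2)))
        sd = np.sqrt(mu + alpha * mu ** 2)
        resid = (y - mu) / np.where(sd > 0, sd, 1.0)
        sd_ref = np.sqrt(mu_ref + alpha * mu_ref ** 2)
        out[:, g] = np.clip(mu_ref + resid * sd_ref, 0.0, None)
    return out


def jitter_zero_variance(matrix: np.ndarray, groups, halfwidth: float = 0.01,
                         seed: int = 0, group_a=None, group_b=None
                         ) -> np.ndarray:
    """Break exact within-group ties: genes whose nonzero values have zero
    variance in either group receive U(-halfwidth, +halfwidth) noise on all
    their values (clipped at 0); every other gene is returned bit-identical.
    """
    X = np.asarray(matrix, dtype=float).copy()
    ma, mb = _two_groups(groups, group_a, group_b)
    rng = np.random.default_rng(seed)
    for g in range(X.shape[1]):
        flagged = False
        for m in (ma, mb):
            nz = X[m, g][X[m, g] != 0]
            if len(nz) >= 1 and np.ptp(nz) == 0:
                flagged = True
                break
        if flagged:
            X[:, g] = np.clip(
                X[:, g] + rng.uniform(-halfwidth, halfwidth, size=X.shape[0]),
                0.0, None)
    return X


def test_dz(matrix: np.ndarray, groups, group_a=None, group_b=None
            ) -> pd.DataFrame:
    """Per-gene two-sided Fisher's exact test on the zero/nonzero x group
    table. Returns columns ``p_zero`` and ``zp_diff`` (ZP(A) - ZP(B), in
    percentage points)."""
    X = np.asarray(matrix)
    ma, mb = _two_groups(groups, group_a, group_b)
    na, nb = int(ma.sum()), int(mb.sum())
    za = (X[ma] == 0).sum(axis=0)
    zb = (X[mb] == 0).sum(axis=0)
    cache: dict[tuple[int, int], float] = {}
    p = np.empty(X.shape[1])
    for g in range(X.shape[1]):
        key = (int(za[g]), int(zb[g]))
        if key not in cache:
            table = [[key[0], na - key[0]], [key[1], nb - key[1]]]
            cache[key] = float(stats.fisher_exact(table,
                                                  alternative="two-sided")[1])
        p[g] = cache[key]
    zp_diff = (za / na - zb / nb) * 100.0
    return pd.DataFrame({"p_zero": p, "zp_diff": zp_diff})


def _bic_gauss1(x: np.ndarray) -> float:
    n = len(x)
    var = max(x.var(), 1e-12)
    loglik = -0.5 * n * (np.log(2 * np.pi * var) + 1.0)
    return 2 * np.log(n) - 2 * loglik


def _fit_modality(logx: np.ndarray, merge_tol: float, seed: int
                  ) -> tuple[int, float, np.ndarray]:
    """(effective number of modes, BIC1 - BIC2, sorted component means)."""
    bic1 = _bic_gauss1(logx)
    gm = GaussianMixture(n_components=2, random_state=seed, n_init=1,
                         reg_covar=1e-6, max_iter=200)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gm.fit(logx.reshape(-1, 1))
    bic2 = float(gm.bic(logx.reshape(-1, 1)))
    means = np.sort(gm.means_.ravel())
    delta = bic1 - bic2  # > 0 favours two components
    k = 2 if (bic2 < bic1 and means[1] - means[0] >= merge_tol) else 1
    return k, delta, means if k == 2 else np.array([logx.mean()])


def test_nonzero(matrix: np.ndarray, groups, group_a=None, group_b=None,
                 merge_tol: float = 1.0, n_perm: int = 100, seed: int = 0
                 ) -> pd.DataFrame:
    """Per-gene test on the nonzero expression values.

    Modality per group is chosen by BIC between 1- and 2-component Gaussian
    mixtures of the log values (components closer than ``merge_tol`` are
    merged). Differing modality (or matched modes displaced beyond the
    tolerance) makes the gene a DM candidate, tested by permuting group
    labels of the nonzero values on the modality statistic; otherwise a
    two-sided Mann-Whitney test on the log values gives the DE p-value.
    Genes with fewer than 3 nonzero cells in either group get p = 1.
    """
    X = np.asarray(matrix, dtype=float)
    ma, mb = _two_groups(groups, group_a, group_b)
    rng = np.random.default_rng(seed)
    rows = []
    for g in range(X.shape[1]):
        a = X[ma, g]
        b = X[mb, g]
        nza, nzb = a[a > 0], b[b > 0]
        mean_a = nza.mean() if len(nza) else np.nan
        mean_b = nzb.mean() if len(nzb) else np.nan
        with np.errstate(divide="ignore", invalid="ignore"):
            lfc = float(np.log2(mean_a / mean_b)) if len(nza) and len(nzb) \
                else np.nan
        if len(nza) < 3 or len(nzb) < 3:
            rows.append(dict(p_nonzero=1.0, log2_fc=lfc, k_a=0, k_b=0,
                             dm_candidate=False))
            continue
        la, lb = np.log(nza), np.log(nzb)
        ka, da, mu_a = _fit_modality(la, merge_tol, seed)
        kb, db, mu_b = _fit_modality(lb, merge_tol, seed)
        dm = ka != kb
        if not dm and ka == 2:
            dm = bool(np.any(np.abs(mu_a - mu_b) > merge_tol))
        if dm:
            obs = abs(da - db)
            pooled = np.concatenate([la, lb])
            hits = 0
            for _ in range(n_perm):
                perm = rng.permutation(pooled)
                pa, pb = perm[:len(la)], perm[len(la):]
                _, da_p, _ = _fit_modality(pa, merge_tol, seed)
                _, db_p, _ = _fit_modality(pb, merge_tol, seed)
                if abs(da_p - db_p) >= obs:
                    hits += 1
            p = (1 + hits) / (n_perm + 1)
        else:
            p = float(stats.mannwhitneyu(la, lb,
                                         alternative="two-sided").pvalue)
        rows.append(dict(p_nonzero=p, log2_fc=lfc, k_a=ka, k_b=kb,
                         dm_candidate=bool(dm)))
    return pd.DataFrame(rows)


def classify_genes(dz_results: pd.DataFrame, nonzero_results: pd.DataFrame,
                   p: DDParams | None = None,
                   genes=None) -> pd.DataFrame:
    """Combine the two branches into one DD call per gene.

    Both p-value families are BH-adjusted separately; DZ requires
    fdr_zero < cutoff and |zp_diff| >= min_zp_diff; DE/DM require
    fdr_nonzero < cutoff plus the fold-change gate (DE always, DM only if
    ``dm_requires_fc``). When a gene qualifies on both branches the one
    with the smaller FDR wins, DZ on ties.
    """
    p = p or DDParams()
    if len(dz_results) != len(nonzero_results):
        raise ValueError("gene sets of the two branches do not match")
    n = len(dz_results)
    fdr_zero = multipletests(dz_results["p_zero"], method="fdr_bh")[1]
    fdr_nz = multipletests(nonzero_results["p_nonzero"], method="fdr_bh")[1]
    cats = []
    for i in range(n):
        dz_hit = fdr_zero[i] < p.fdr_cutoff and \
            abs(dz_results["zp_diff"].iloc[i]) >= p.min_zp_diff
        lfc = nonzero_results["log2_fc"].iloc[i]
        dm = bool(nonzero_results["dm_candidate"].iloc[i])
        fc_ok = np.isfinite(lfc) and abs(lfc) >= p.min_abs_log2fc
        if dm:
            nz_hit = fdr_nz[i] < p.fdr_cutoff and (fc_ok or not p.dm_requires_fc)
            nz_cat = "DM"
        else:
            nz_hit = fdr_nz[i] < p.fdr_cutoff and fc_ok
            nz_cat = "DE"
        if dz_hit and nz_hit:
            cat = "DZ" if fdr_zero[i] <= fdr_nz[i] else nz_cat
        elif dz_hit:
            cat = "DZ"
        elif nz_hit:
            cat = nz_cat
        else:
            cat = "none"
        cats.append(cat)
    out = pd.DataFrame({
        "gene": list(genes) if genes is not None else np.arange(n),
        "category": cats,
        "p_nonzero": nonzero_results["p_nonzero"].to_numpy(),
        "p_zero": dz_results["p_zero"].to_numpy(),
        "fdr_nonzero": fdr_nz,
        "fdr_zero": fdr_zero,
        "log2_fc": nonzero_results["log2_fc"].to_numpy(),
        "zp_diff": dz_results["zp_diff"].to_numpy(),
    })
    return out


def run_dd(counts: np.ndarray, groups, genes=None, batch=None,
           params: DDParams | None = None, seed: int = 0,
           depth_correct: bool = True, group_a=None, group_b=None
           ) -> pd.DataFrame:
    """End-to-end DD calling on a counts matrix (cells x genes)."""
    params = params or DDParams()
    X = np.asarray(counts, dtype=float)
    groups = np.asarray(groups)
    if depth_correct:
        X = correct_depth(X, batch=batch)
    if params.depth_window is not None:
        lo, hi = params.depth_window
        tot = X.sum(axis=1)
        keep = (tot >= lo) & (tot <= hi)
        X, groups = X[keep], groups[keep]
    # the zero-proportion branch sees the raw zeros; the jitter guard only
    # protects the nonzero-distribution branch from exact within-group ties
    dz = test_dz(X, groups, group_a, group_b)
    X = jitter_zero_variance(X, groups, params.jitter_halfwidth, seed,
                             group_a, group_b)
    nz = test_nonzero(X, groups, group_a, group_b,
                      merge_tol=params.merge_tol, n_perm=params.n_perm,
                      seed=seed)
    return classify_genes(dz, nz, params, genes=genes)
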