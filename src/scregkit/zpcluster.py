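"""Zero-proportion profiles across cell states and their clustering.

The detection metric ZP is the fraction of cells in a state with a zero
count for a gene. Gene ZP profiles are grouped by Lloyd-style k-means
using Pearson correlation as the distance (d = 1 - r), the pairing used
by k-centroids families for shape-based clustering: a profile's scale
and offset do not matter, only its shape across states.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_score

logger = logging.getLogger(__name__)

FLAT_CLUSTER = -1  # pseudo-cluster for constant (uncorrelatable) profiles


def zp_profile(counts, state_labels, genes=None, states=None) -> pd.DataFrame:
    """Exact per-gene, per-state zero-count fraction.

    ``counts`` is cells x genes (ndarray or DataFrame with gene columns).
    Returns genes x states with values in [0, 1].
    """
    if isinstance(counts, pd.DataFrame):
        gene_names = list(counts.columns)
        X = counts.to_numpy()
    else:
        X = np.asarray(counts)
        gene_names = [f"g{i}" for i in range(X.shape[1])]
    labels = np.asarray(state_labels)
    if states is None:
        states = list(pd.unique(labels))
    if genes is None:
        genes = gene_names
    gidx = {g: i for i, g in enumerate(gene_names)}
    missing = [g for g in genes if g not in gidx]
    if missing:
        raise KeyError(f"unknown genes: {missing[:5]}")
    cols = {}
    for s in states:
        mask = labels == s
        if mask.sum() == 0:
            raise ValueError(f"state {s!r} has no cells")
        cols[s] = (X[mask][:, [gidx[g] for g in genes]] == 0).mean(axis=0)
    return pd.DataFrame(cols, index=pd.Index(genes, name="gene"))


@dataclass
class KMeansResult:
    assignments: pd.Series      # gene -> cluster id (FLAT_CLUSTER for flat)
    centroids: np.ndarray       # k x n_states
    objective: float            # total within-cluster (1 - r)
    n_iter: int


def _zscore_rows(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    return (X - mu) / np.where(sd > 0, sd, 1.0)


def _corr_to_centroids(Z: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    Zc = _zscore_rows(centroids)
    return Z @ Zc.T / Z.shape[1]


def _lloyd(X: np.ndarray, Z: np.ndarray, init: np.ndarray, max_iter: int,
           ) -> tuple[np.ndarray, np.ndarray, float, int]:
    centroids = init.copy()
    assign = np.full(X.shape[0], -1)
    for it in range(max_iter):
        corr = _corr_to_centroids(Z, centroids)
        new_assign = corr.argmax(axis=1)
        best = corr[np.arange(len(new_assign)), new_assign]
        for c in range(centroids.shape[0]):
            if not np.any(new_assign == c):  # reseed from worst-fit profile
                worst = int(np.argmin(best))
                new_assign[worst] = c
                best[worst] = 1.0
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for c in range(centroids.shape[0]):
            centroids[c] = X[assign == c].mean(axis=0)
    corr = _corr_to_centroids(Z, centroids)
    obj = float((1.0 - corr[np.arange(len(assign)), assign]).sum())
    return assign, centroids, obj, it + 1


def kmeans_correlation(profiles, k: int = 8, max_iter: int = 100,
                       n_init: int = 10, seed: int = 0,
                       extra_inits=None) -> KMeansResult:
    """Correlation-distance k-means of ZP profiles.

    Assignment maximizes Pearson correlation to the centroid (distance
    1 - r); the centroid update is the plain mean of member profiles; empty
    clusters are reseeded from the worst-fit profile; the best of ``n_init``
    random restarts (by total within-cluster distance) wins. Constant
    profiles cannot be correlated and are pre-assigned to a dedicated flat
    pseudo-cluster (id -1), logged.
    """
    if isinstance(profiles, pd.DataFrame):
        names = profiles.index
        X = profiles.to_numpy(dtype=float)
    else:
        X = np.asarray(profiles, dtype=float)
        names = pd.RangeIndex(X.shape[0])
    variable = X.std(axis=1) > 0
    n_flat = int((~variable).sum())
    if n_flat:
        logger.info("%d constant profiles moved to the flat pseudo-cluster",
                    n_flat)
    Xv = X[variable]
    if k > Xv.shape[0]:
        raise ValueError("k exceeds the number of variable profiles")
    Z = _zscore_rows(Xv)
    rng = np.random.default_rng(seed)
    inits = []
    for _ in range(n_init):
        pick = rng.choice(Xv.shape[0], size=k, replace=False)
        inits.append(Xv[pick])
    if extra_inits is not None:
        inits.extend(np.asarray(e, dtype=float) for e in extra_inits)
    best = None
    for init in inits:
        assign, cent, obj, n_it = _lloyd(Xv, Z, init, max_iter)
        if best is None or obj < best[2] - 1e-12:
            best = (assign, cent, obj, n_it)
    assign_full = np.full(X.shape[0], FLAT_CLUSTER)
    assign_full[variable] = best[0]
    return KMeansResult(
        assignments=pd.Series(assign_full, index=names, name="cluster"),
        centroids=best[1], objective=best[2], n_iter=best[3])


def scan_k(profiles, k_range=range(6, 11), seed: int = 0, n_init: int = 10,
           max_iter: int = 100) -> pd.DataFrame:
    """Diagnostics per candidate k: total within-cluster distance and mean
    silhouette under the correlation distance.

    Each k is warm-started from the previous best solution (its centroids
    plus the worst-fit profile as the extra centroid), so the best
    objective is non-increasing in k.
    """
    if isinstance(profiles, pd.DataFrame):
        X = profiles.to_numpy(dtype=float)
    else:
        X = np.asarray(profiles, dtype=float)
    variable = X.std(axis=1) > 0
    Xv = X[variable]
    Z = _zscore_rows(Xv)
    D = 1.0 - Z @ Z.T / Z.shape[1]
    np.fill_diagonal(D, 0.0)
    D = np.clip(D, 0.0, None)
    rows = []
    prev: KMeansResult | None = None
    for k in sorted(k_range):
        extra = None
        if prev is not None and prev.centroids.shape[0] == k - 1:
            corr = _corr_to_centroids(
                Z, prev.centroids)[np.arange(Z.shape[0]),
                                   prev.assignments[variable].to_numpy()]
            worst = Xv[int(np.argmin(corr))]
            extra = [np.vstack([prev.centroids, worst])]
        res = kmeans_correlation(profiles, k=k, max_iter=max_iter,
                                 n_init=n_init, seed=seed, extra_inits=extra)
        lab = res.assignments.to_numpy()[variable]
        if 1 < k < Xv.shape[0]:
            sil = float(silhouette_score(D, lab, metric="precomputed")) \
                if len(np.unique(lab)) > 1 else np.nan
        else:
            sil = np.nan
        rows.append(dict(k=k, within_dist=res.objective, silhouette=sil))
        prev = res
    return pd.DataFrame(rows)
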