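"""Cross-validated regulon discovery and TF activity scoring.

One discovery iteration: sample an equal number of cells per cell type,
replace zero entries of the normalized matrix with small uniform noise
(so repressive targets contribute negative correlations), infer signed
TF-target links by Pearson correlation, prune them against a motif
annotation table, split the balanced matrix 70/30 into train/test,
rediscover on the train set, and keep only regulons whose mean per-type
AUC recovery scores reproduce in the test set (correlation p <= 0.001).
Ten iterations are merged by (TF, sign); each target carries Npred, the
number of iterations that supported it, and per-cell activity is the
mean AUC score over iterations on the full dataset. Three post-hoc
filters remove regulons whose score does not track cell type (mean
R-squared of score ~ cell type below 0.5 over 100 balanced refits),
regulons highly active in a cell type while the TF itself is almost
never detected, and regulons anti-correlated with their own TF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class Regulon:
    """A TF with a signed target set; targets map to Npred support counts."""

    tf: str
    sign: str  # "+" activating, "-" repressive
    targets: dict[str, int]
    n_iterations_found: int = 1

    def __post_init__(self) -> None:
        if self.sign not in ("+", "-"):
            raise ValueError("sign must be '+' or '-'")
        if not self.targets:
            raise ValueError("targets must be non-empty")
        if self.tf in self.targets:
            raise ValueError("tf must not be among its own targets")

    @property
    def name(self) -> str:
        return f"{self.tf}({self.sign})"


@dataclass
class CVParams:
    train_frac: float = 0.70
    cv_p_cutoff: float = 0.001
    n_iter: int = 10
    n_cells_lm: int = 600
    n_fits_lm: int = 100
    r2_min: float = 0.5
    pct_threshold: float = 70.0
    tf_zero_frac: float = 0.96
    tf_corr_min: float = -0.8
    balanced_n: int = 600
    top_n_targets: int = 50
    sign_threshold: float = 0.03
    min_targets: int = 10
    top_fraction: float = 0.05
    noise_halfwidth: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_frac < 1:
            raise ValueError("train_frac must be in (0, 1)")
        if not 0 < self.cv_p_cutoff < 1:
            raise ValueError("cv_p_cutoff must be in (0, 1)")
        if self.n_iter < 1 or self.min_targets < 1:
            raise ValueError("n_iter and min_targets must be >= 1")
        if not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction must be in (0, 1]")


# ---------------------------------------------------------------------------
# sampling and noise

def balanced_sample(labels, n_per_type: int, rng) -> np.ndarray:
    """Positions of an equal-per-type subsample: n = min(n_per_type,
    smallest type size) cells per label, without replacement."""
    labels = np.asarray(labels)
    types, counts = np.unique(labels, return_counts=True)
    n = int(min(n_per_type, counts.min()))
    picks = []
    for t in types:
        pos = np.where(labels == t)[0]
        picks.append(rng.choice(pos, size=n, replace=False))
    return np.sort(np.concatenate(picks))


def inject_zero_noise(matrix: np.ndarray, halfwidth: float = 0.01,
                      rng=None, seed: int = 0) -> np.ndarray:
    """Replace every zero entry by U(-halfwidth, +halfwidth); nonzero
    entries are untouched."""
    rng = rng if rng is not None else np.random.default_rng(seed)
    X = np.asarray(matrix, dtype=float).copy()
    zeros = X == 0
    X[zeros] = rng.uniform(-halfwidth, halfwidth, size=int(zeros.sum()))
    return X


# ---------------------------------------------------------------------------
# link inference and motif pruning

def infer_links(matrix: np.ndarray, gene_names, tf_list,
                top_n_targets: int = 50,
                sign_threshold: float = 0.03) -> pd.DataFrame:
    """Signed TF-target candidate edges by Pearson correlation.

    Per TF the ``top_n_targets`` genes by |r| are kept; the sign is + for
    r > sign_threshold, - for r < -sign_threshold, otherwise the edge is
    dropped. Constant TF vectors are skipped with a warning.
    """
    X = np.asarray(matrix, dtype=float)
    gene_names = list(gene_names)
    gidx = {g: i for i, g in enumerate(gene_names)}
    Z = X - X.mean(axis=0, keepdims=True)
    sd = Z.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        Z = np.where(sd > 0, Z / sd, 0.0)
    rows = []
    for tf in tf_list:
        if tf not in gidx:
            continue
        ti = gidx[tf]
        if sd[ti] == 0:
            logger.warning("TF %s has constant expression; skipped", tf)
            continue
        r = Z[:, ti] @ Z / X.shape[0]
        r[ti] = 0.0
        order = np.argsort(-np.abs(r), kind="stable")[:top_n_targets]
        for gi in order:
            rv = float(r[gi])
            if rv > sign_threshold:
                rows.append((tf, gene_names[gi], rv, "+"))
            elif rv < -sign_threshold:
                rows.append((tf, gene_names[gi], rv, "-"))
    return pd.DataFrame(rows, columns=["tf", "gene", "r", "sign"])


def prune_by_motif(edges: pd.DataFrame, motif_table: pd.DataFrame,
                   min_targets: int = 10) -> list[Regulon]:
    """Keep edges with motif support, split by sign into regulons, and drop
    regulons with fewer than ``min_targets`` targets."""
    if len(edges) == 0:
        return []
    supported = set(zip(motif_table["tf"], motif_table["gene"])) \
        if len(motif_table) else set()
    tfs_with_motifs = {tf for tf, _ in supported}
    regulons: list[Regulon] = []
    for (tf, sign), grp in edges.groupby(["tf", "sign"], sort=True):
        targets = [g for g in grp["gene"] if (tf, g) in supported]
        if tf not in tfs_with_motifs:
            logger.info("TF %s absent from motif table; regulon dropped", tf)
        if len(targets) >= min_targets:
            regulons.append(Regulon(tf=tf, sign=sign,
                                    targets={g: 1 for g in targets}))
    return regulons


# ---------------------------------------------------------------------------
# AUC recovery scoring

def rank_genes(matrix: np.ndarray, seed: int = 0) -> np.ndarray:
    """Per-cell 1-based gene ranks by decreasing expression; ties broken by
    one seeded random gene permutation fixed for the whole run."""
    X = np.asarray(matrix)
    n_cells, n_genes = X.shape
    perm = np.random.default_rng(seed).permutation(n_genes)
    order = np.argsort(-X[:, perm], axis=1, kind="stable")
    gene_order = perm[order]  # gene index at each rank position
    ranks = np.empty_like(gene_order)
    np.put_along_axis(ranks, gene_order,
                      np.broadcast_to(np.arange(1, n_genes + 1),
                                      (n_cells, n_genes)), axis=1)
    return ranks


def auc_from_ranks(ranks: np.ndarray, gene_idx, top_fraction: float = 0.05
                   ) -> np.ndarray:
    """AUC of the step recovery curve over ranks 1..k, normalized by its
    maximum; k = ceil(top_fraction x n_genes)."""
    gene_idx = np.asarray(gene_idx, dtype=int)
    if gene_idx.size == 0:
        raise ValueError("no regulon gene present in the matrix")
    n_genes = ranks.shape[1]
    k = int(np.ceil(top_fraction * n_genes))
    m = len(gene_idx)
    if m <= k:
        max_sum = m * (m + 1) / 2 + (k - m) * m
    else:
        max_sum = k * (k + 1) / 2
    r = ranks[:, gene_idx]
    contrib = np.clip(k - r + 1, 0, None)
    return contrib.sum(axis=1) / max_sum


def auc_score(matrix: np.ndarray, gene_names, regulon: Regulon,
              top_fraction: float = 0.05, seed: int = 0) -> np.ndarray:
    """Per-cell AUC recovery score of a regulon's target set, in [0, 1]."""
    gidx = {g: i for i, g in enumerate(gene_names)}
    idx = [gidx[g] for g in regulon.targets if g in gidx]
    if not idx:
        raise ValueError("no regulon gene present in the matrix")
    ranks = rank_genes(matrix, seed=seed)
    return auc_from_ranks(ranks, idx, top_fraction)


# ---------------------------------------------------------------------------
# cross-validation gate

def cv_gate(train_means: np.ndarray, test_means: np.ndarray,
            p_cutoff: float = 0.001) -> tuple[bool, float, float]:
    """Reproducibility gate: Pearson r between the per-type mean score
    vectors of the train and test split, with a two-sided t-test on
    n_types - 2 degrees of freedom. Undefined r (constant vector) fails."""
    x = np.asarray(train_means, dtype=float)
    y = np.asarray(test_means, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("correlation needs at least 3 cell types")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return False, np.nan, np.nan
    r = float(np.corrcoef(x, y)[0, 1])
    r = min(1.0, max(-1.0, r))
    if abs(r) == 1.0:
        return True, r, 0.0
    t = r * np.sqrt((n - 2) / (1 - r * r))
    p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return p <= p_cutoff, r, p


def _stratified_split(labels: np.ndarray, train_frac: float, rng
                      ) -> tuple[np.ndarray, np.ndarray]:
    train, test = [], []
    for t in np.unique(labels):
        pos = np.where(labels == t)[0]
        pos = rng.permutation(pos)
        n_train = int(round(train_frac * len(pos)))
        n_train = min(max(n_train, 1), len(pos) - 1)
        train.append(pos[:n_train])
        test.append(pos[n_train:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


def _mean_by_type(scores: np.ndarray, labels: np.ndarray,
                  types: np.ndarray) -> np.ndarray:
    return np.array([scores[labels == t].mean() for t in types])


def crossvalidate(matrix: np.ndarray, labels, gene_names, motif_table,
                  p: CVParams, rng, tf_list=None) -> list[Regulon]:
    """One discovery round with a train/test reproducibility gate.

    The (already balanced) matrix is split 70/30 stratified by cell type,
    regulons are discovered on the noise-injected train split, scored on
    both splits, and retained when the per-type mean scores correlate with
    p <= ``cv_p_cutoff``.
    """
    labels = np.asarray(labels)
    types = np.unique(labels)
    if len(types) < 3:
        raise ValueError("crossvalidate requires at least 3 cell types")
    if tf_list is None:
        tf_list = sorted(set(motif_table["tf"]))
    tr, te = _stratified_split(labels, p.train_frac, rng)
    X = np.asarray(matrix, dtype=float)
    noisy_train = inject_zero_noise(X[tr], p.noise_halfwidth, rng=rng)
    edges = infer_links(noisy_train, gene_names, tf_list,
                        p.top_n_targets, p.sign_threshold)
    candidates = prune_by_motif(edges, motif_table, p.min_targets)
    if not candidates:
        return []
    tie_seed = int(rng.integers(0, 2 ** 31 - 1))
    ranks_tr = rank_genes(X[tr], seed=tie_seed)
    ranks_te = rank_genes(X[te], seed=tie_seed)
    gidx = {g: i for i, g in enumerate(gene_names)}
    retained = []
    for reg in candidates:
        idx = [gidx[g] for g in reg.targets]
        s_tr = auc_from_ranks(ranks_tr, idx, p.top_fraction)
        s_te = auc_from_ranks(ranks_te, idx, p.top_fraction)
        ok, r, pval = cv_gate(_mean_by_type(s_tr, labels[tr], types),
                              _mean_by_type(s_te, labels[te], types),
                              p.cv_p_cutoff)
        if ok:
            retained.append(reg)
    return retained


# ---------------------------------------------------------------------------
# full discovery with merging

def run_discovery(matrix: np.ndarray, labels, gene_names, motif_table,
                  p: CVParams | None = None, tf_list=None
                  ) -> tuple[list[Regulon], pd.DataFrame]:
    """``n_iter`` independent discovery rounds merged by (TF, sign).

    ``matrix`` is the log-normalized expression of the full dataset
    (cells x genes). Per round: balanced per-type sampling, cross-validated
    discovery, then AUC scoring of the survivors on the full dataset.
    Npred of a target is the number of rounds whose regulon contained it;
    the reported activity is the mean over rounds of the full-data scores.
    Returns (regulons, activity) where activity is cells x regulons.
    """
    p = p or CVParams()
    X = np.asarray(matrix, dtype=float)
    labels = np.asarray(labels)
    found: dict[tuple[str, str], dict] = {}
    full_rank_seed = int(np.random.default_rng([p.seed, 77]).integers(2 ** 31))
    full_ranks = rank_genes(X, seed=full_rank_seed)
    gidx = {g: i for i, g in enumerate(gene_names)}
    for it in range(p.n_iter):
        rng = np.random.default_rng([p.seed, 100 + it])
        sel = balanced_sample(labels, p.balanced_n, rng)
        survivors = crossvalidate(X[sel], labels[sel], gene_names,
                                  motif_table, p, rng, tf_list=tf_list)
        for reg in survivors:
            key = (reg.tf, reg.sign)
            idx = [gidx[g] for g in reg.targets]
            score = auc_from_ranks(full_ranks, idx, p.top_fraction)
            slot = found.setdefault(key, {"targets": {}, "scores": [],
                                          "n_found": 0})
            slot["n_found"] += 1
            slot["scores"].append(score)
            for g in reg.targets:
                slot["targets"][g] = slot["targets"].get(g, 0) + 1
    if not found:
        logger.info("no regulon survived discovery")
        return [], pd.DataFrame(index=np.arange(X.shape[0]))
    regulons = []
    cols = {}
    for (tf, sign), slot in sorted(found.items()):
        reg = Regulon(tf=tf, sign=sign, targets=dict(sorted(
            slot["targets"].items())), n_iterations_found=slot["n_found"])
        regulons.append(reg)
        cols[reg.name] = np.mean(slot["scores"], axis=0)
    activity = pd.DataFrame(cols)
    return regulons, activity


# ---------------------------------------------------------------------------
# post-hoc filters

def filter_linear_model(activity: pd.DataFrame, labels, p: CVParams,
                        seed: int | None = None
                        ) -> tuple[list[str], pd.Series]:
    """Retain regulons whose score is explained by cell type: mean
    R-squared of OLS score ~ one-hot(type) over ``n_fits_lm`` balanced
    subsamples of ``n_cells_lm`` cells per type must reach ``r2_min``."""
    labels = np.asarray(labels)
    types = np.unique(labels)
    rng = np.random.default_rng(p.seed if seed is None else seed)
    A = activity.to_numpy(dtype=float)
    r2_sum = np.zeros(A.shape[1])
    for _ in range(p.n_fits_lm):
        sel = balanced_sample(labels, p.n_cells_lm, rng)
        y = A[sel]
        lab = labels[sel]
        resid_ss = np.zeros(A.shape[1])
        for t in types:
            sub = y[lab == t]
            resid_ss += ((sub - sub.mean(axis=0)) ** 2).sum(axis=0)
        tot_ss = ((y - y.mean(axis=0)) ** 2).sum(axis=0)
        constant = np.ptp(y, axis=0) == 0  # exact check; tot_ss can be ~eps
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = np.where((tot_ss > 0) & ~constant,
                          1.0 - resid_ss / tot_ss, 0.0)
        r2_sum += r2
    mean_r2 = pd.Series(r2_sum / p.n_fits_lm, index=activity.columns,
                        name="mean_r2")
    kept = [c for c in activity.columns if mean_r2[c] >= p.r2_min]
    return kept, mean_r2


def filter_expression_support(activity: pd.DataFrame, tf_expression,
                              regulons: list[Regulon], labels,
                              pct_threshold: float = 70.0,
                              tf_zero_frac: float = 0.96
                              ) -> tuple[list[str], pd.DataFrame]:
    """Drop regulons that look active (some cell type's mean score above the
    regulon's own ``pct_threshold`` percentile over all cells) while the TF
    itself is practically undetected (> ``tf_zero_frac`` zeros, strict)."""
    labels = np.asarray(labels)
    types = np.unique(labels)
    tf_expression = pd.DataFrame(tf_expression)
    by_name = {r.name: r for r in regulons}
    rows = []
    kept = []
    for name in activity.columns:
        reg = by_name[name]
        scores = activity[name].to_numpy()
        q = np.percentile(scores, pct_threshold)
        type_means = np.array([scores[labels == t].mean() for t in types])
        if reg.tf not in tf_expression.columns:
            logger.warning("TF %s not in expression matrix; regulon removed",
                           reg.tf)
            rows.append((name, np.nan, float(type_means.max()), q, False))
            continue
        zf = float((tf_expression[reg.tf].to_numpy() == 0).mean())
        suspicious = bool((type_means > q).any() and zf > tf_zero_frac)
        rows.append((name, zf, float(type_means.max()), q, not suspicious))
        if not suspicious:
            kept.append(name)
    report = pd.DataFrame(rows, columns=["regulon", "tf_zero_frac",
                                         "max_type_mean", "score_pctl",
                                         "kept"])
    return kept, report


def filter_tf_correlation(activity: pd.DataFrame, tf_expression,
                          regulons: list[Regulon],
                          tf_corr_min: float = -0.8
                          ) -> tuple[list[str], pd.Series]:
    """Drop regulons whose per-cell score has Pearson r strictly below
    ``tf_corr_min`` with their own TF's expression. Undefined correlations
    (constant vectors, missing TF) are kept, logged."""
    tf_expression = pd.DataFrame(tf_expression)
    by_name = {r.name: r for r in regulons}
    kept, rs = [], {}
    for name in activity.columns:
        reg = by_name[name]
        scores = activity[name].to_numpy(dtype=float)
        if reg.tf not in tf_expression.columns:
            logger.warning("TF %s not in expression matrix; correlation "
                           "undefined, regulon kept", reg.tf)
            rs[name] = np.nan
            kept.append(name)
            continue
        x = tf_expression[reg.tf].to_numpy(dtype=float)
        if np.ptp(scores) == 0 or np.ptp(x) == 0:
            logger.warning("constant vector for %s; correlation undefined, "
                           "regulon kept", name)
            rs[name] = np.nan
            kept.append(name)
            continue
        r = float(np.corrcoef(scores, x)[0, 1])
        rs[name] = r
        if not r < tf_corr_min:
            kept.append(name)
    return kept, pd.Series(rs, name="tf_corr")


def run_full_pipeline(matrix: np.ndarray, labels, gene_names, motif_table,
                      p: CVParams | None = None, tf_list=None
                      ) -> dict:
    """Discovery plus the three post-hoc filters.

    Returns a dict with the merged regulons, the retained regulon names,
    the activity matrix restricted to survivors, and a per-regulon filter
    report (mean R-squared, TF zero fraction, TF correlation, decisions).
    """
    p = p or CVParams()
    regulons, activity = run_discovery(matrix, labels, gene_names,
                                       motif_table, p, tf_list=tf_list)
    if not regulons:
        return {"regulons": [], "kept": [], "activity": activity,
                "report": pd.DataFrame()}
    gene_names = list(gene_names)
    X = np.asarray(matrix, dtype=float)
    tf_cols = sorted({r.tf for r in regulons} & set(gene_names))
    tf_expr = pd.DataFrame(
        {tf: X[:, gene_names.index(tf)] for tf in tf_cols})
    lm_seed = int(np.random.default_rng([p.seed, 55]).integers(2 ** 31))
    kept_lm, mean_r2 = filter_linear_model(activity, labels, p, seed=lm_seed)
    kept_expr, expr_report = filter_expression_support(
        activity[kept_lm], tf_expr, regulons, labels,
        p.pct_threshold, p.tf_zero_frac)
    kept_corr, tf_corr = filter_tf_correlation(
        activity[kept_expr], tf_expr, regulons, p.tf_corr_min)
    report = pd.DataFrame({"regulon": activity.columns})
    report["mean_r2"] = report["regulon"].map(mean_r2)
    report["passed_lm"] = report["regulon"].isin(kept_lm)
    report["tf_zero_frac"] = report["regulon"].map(
        expr_report.set_index("regulon")["tf_zero_frac"])
    report["passed_expression"] = report["regulon"].isin(kept_expr)
    report["tf_corr"] = report["regulon"].map(tf_corr)
    report["passed_tf_corr"] = report["regulon"].isin(kept_corr)
    report["kept"] = report["regulon"].isin(kept_corr)
    kept_regs = [r for r in regulons if r.name in set(kept_corr)]
    return {"regulons": kept_regs, "all_regulons": regulons,
            "kept": kept_corr, "activity": activity[kept_corr],
            "report": report}
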