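"""Ground-truthed synthetic bone-marrow-like scRNA-seq data.

The generator emulates the statistical structure the downstream stages
assume: a ladder of cell states with alternating cycling/G1 phases,
planted activating and repressive TF regulons, library-size variation,
donor effects, negative-binomial counts with mean-dependent dropout
(producing state-dependent zero proportions), a motif-annotation table
with controllable true/false-positive rates, and peak files placed near
true regulon targets on a single synthetic chromosome.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from scipy.special import expit


@dataclass
class SimulationConfig:
    """Parameters of the synthetic dataset.

    Defaults describe the standard study conditions used throughout the
    test-suite: 8 cell states x 200 cells, 2,000 genes, 10 planted
    regulons (3 repressive) driven at a log2 effect of 1.5, motif table
    at 90% sensitivity.
    """

    n_states: int = 8
    cells_per_state: int = 200
    n_genes: int = 2000
    n_tfs: int = 20
    n_planted_regulons: int = 10
    targets_per_regulon: int = 50
    target_abundance_quantile: float = 0.7  # regulated genes are detectable
    regulon_effect: float = 1.5      # log2 fold change per unit TF activity
    repressive_fraction: float = 0.3
    libsize_mu: float = float(np.log(5000.0))
    libsize_sigma: float = 0.35
    dropout_midpoint: float = float(np.log(0.5))  # logistic midpoint on ln(mean)
    dropout_slope: float = 1.0
    n_donors: int = 3
    donor_effect_sd: float = 0.15    # ln-scale SD of donor x gene factors
    motif_tpr: float = 0.9
    motif_fpr: float = 0.01
    peak_tpr: float = 0.8
    peak_fpr: float = 0.05
    seed: int = 0
    # secondary structure (fixed study conditions, rarely changed)
    state_effect_sd: float = 0.5     # log2 SD of per-state baseline modulation
    activity_noise_sd: float = 0.4   # per-cell latent TF-activity jitter
    n_mito_genes: int = 10
    mito_frac_target: float = 0.05  # expected mitochondrial UMI share
    n_cycle_genes: int = 50
    cycle_effect: float = 1.5        # log2 boost of cycle genes in cycling states
    n_outlier_libsize: int = 5
    n_outlier_mito: int = 5
    plant_dd: bool = True
    n_dd_de: int = 30
    n_dd_dz: int = 30
    n_dd_dm: int = 20
    dd_de_log2fc: float = 2.0
    dd_dz_extra_dropout: float = 0.4
    dd_dm_log2_shift: float = 2.5
    store_means: bool = False

    def __post_init__(self) -> None:
        for name in (
            "n_states", "cells_per_state", "n_genes", "n_tfs",
            "n_planted_regulons", "targets_per_regulon", "n_donors",
        ):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("repressive_fraction", "motif_tpr", "motif_fpr",
                     "peak_tpr", "peak_fpr"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.regulon_effect < 0:
            raise ValueError("regulon_effect must be >= 0")
        if self.n_planted_regulons > self.n_tfs:
            raise ValueError("more planted regulons than TFs")
        n_regular = self.n_genes - self.n_tfs - self.n_mito_genes
        if self.targets_per_regulon * self.n_planted_regulons > n_regular:
            raise ValueError("insufficient genes")


@dataclass
class PlantedRegulon:
    """A planted TF -> target-set edge bundle with its sign and active states."""

    tf: str
    sign: str  # "+" or "-"
    targets: list[str]
    active_states: list[str]


@dataclass
class SyntheticTruth:
    """Everything the generator planted, for downstream scoring against truth."""

    planted_regulons: list[PlantedRegulon]
    tf_names: list[str]
    decoy_tfs: list[str]
    dd_genes: pd.DataFrame  # columns: gene, state_a, state_b, category
    state_labels: pd.Series
    outlier_cells: list[str]
    cycle_genes: list[str]
    gene_dispersion: pd.Series
    expected_means: pd.DataFrame | None = None


def _gene_names(config: SimulationConfig) -> tuple[list[str], list[str], list[str]]:
    tfs = [f"TF{i + 1:03d}" for i in range(config.n_tfs)]
    mito = [f"MT-{i + 1:02d}" for i in range(config.n_mito_genes)]
    n_regular = config.n_genes - config.n_tfs - config.n_mito_genes
    regular = [f"G{i + 1:05d}" for i in range(n_regular)]
    return tfs, regular, mito


def _dropout_probability(mu: np.ndarray, midpoint: float, slope: float) -> np.ndarray:
    if np.isneginf(midpoint):
        return np.zeros_like(mu)
    return expit(-slope * (np.log(mu) - midpoint))


def simulate_counts(config: SimulationConfig) -> tuple[ad.AnnData, SyntheticTruth]:
    """Draw a UMI count matrix with planted regulons, DD genes and QC outliers.

    Per-cell gene means are baseline(state) x regulon multiplier
    (2^(+-effect x latent TF activity)) x donor factor, renormalised to the
    cell's library size; counts are negative-binomial (gamma-Poisson) with a
    per-gene dispersion, thinned by a Bernoulli dropout whose probability is
    logistic in the log mean. Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng([int(config.seed), 0])
    tfs, regular, mito = _gene_names(config)
    genes = tfs + regular + mito
    n_genes = len(genes)
    n_cells = config.n_states * config.cells_per_state
    states = [f"state{i + 1:02d}" for i in range(config.n_states)]
    cycling_state = np.array([i % 2 == 1 for i in range(config.n_states)])

    state_idx = np.repeat(np.arange(config.n_states), config.cells_per_state)
    barcodes = [f"CELL{i + 1:05d}" for i in range(n_cells)]
    donor_idx = rng.integers(0, config.n_donors, size=n_cells)

    # baseline relative abundances
    base = np.empty(n_genes)
    base[: config.n_tfs] = rng.lognormal(1.0, 0.5, size=config.n_tfs)
    base[config.n_tfs:config.n_tfs + len(regular)] = rng.lognormal(
        0.0, 1.0, size=len(regular))
    mito_raw = rng.lognormal(0.0, 0.3, size=config.n_mito_genes)
    # scale mito abundance so the expected mito UMI share hits the target
    other_sum = base[: config.n_tfs + len(regular)].sum()
    tgt = config.mito_frac_target
    base[config.n_tfs + len(regular):] = mito_raw / mito_raw.sum() * \
        other_sum * tgt / (1.0 - tgt)

    # per-state baseline modulation (log2); mito genes are state-flat
    state_log2 = rng.normal(0.0, config.state_effect_sd,
                            size=(config.n_states, n_genes))
    state_log2[:, config.n_tfs + len(regular):] = 0.0

    # planted regulons: disjoint target sets drawn from regular genes
    regular_pool = list(regular)
    n_rep = int(round(config.repressive_fraction * config.n_planted_regulons))
    planted: list[PlantedRegulon] = []
    activities = np.zeros((config.n_planted_regulons, n_cells))
    # regulated targets come from the detectable (upper-half baseline) genes:
    # a target that is almost never observed cannot carry regulon signal
    reg_base = base[config.n_tfs:config.n_tfs + len(regular_pool)]
    need = config.targets_per_regulon * config.n_planted_regulons
    abundant = np.where(reg_base >= np.quantile(
        reg_base, config.target_abundance_quantile))[0]
    pool = abundant if len(abundant) >= need else np.arange(len(regular_pool))
    pool_idx = rng.permutation(pool)
    cursor = 0
    for r in range(config.n_planted_regulons):
        tf = tfs[r]
        sign = "-" if r < n_rep else "+"
        tgt_idx = pool_idx[cursor:cursor + config.targets_per_regulon]
        cursor += config.targets_per_regulon
        targets = [regular_pool[j] for j in tgt_idx]
        k_active = int(rng.integers(2, min(5, config.n_states + 1)))
        active = sorted(rng.choice(config.n_states, size=k_active, replace=False))
        planted.append(PlantedRegulon(
            tf=tf, sign=sign, targets=targets,
            active_states=[states[s] for s in active]))
        # TF dosage varies cell-to-cell where the TF is on; off states are off
        indicator = np.isin(state_idx, active).astype(float)
        a = indicator * (1.0 + rng.normal(0.0, config.activity_noise_sd,
                                          size=n_cells))
        activities[r] = np.clip(a, 0.0, 1.6)

    used = set(pool_idx[:cursor])
    remaining = [j for j in range(len(regular_pool)) if j not in used]

    # cycle genes
    n_cyc = min(config.n_cycle_genes, len(remaining))
    cycle_pos = remaining[:n_cyc]
    remaining = remaining[n_cyc:]
    cycle_genes = [regular_pool[j] for j in cycle_pos]

    # planted differential-distribution genes between the last two states
    dd_rows: list[dict] = []
    extra_dropout = None
    dm_boost = None
    if config.plant_dd and config.n_states >= 2:
        sa, sb = states[-2], states[-1]
        sb_cells = state_idx == config.n_states - 1
        need = config.n_dd_de + config.n_dd_dz + config.n_dd_dm
        if need > len(remaining):
            raise ValueError("insufficient genes")
        de_pos = remaining[:config.n_dd_de]
        dz_pos = remaining[config.n_dd_de:config.n_dd_de + config.n_dd_dz]
        dm_pos = remaining[config.n_dd_de + config.n_dd_dz:need]
        for i, j in enumerate(de_pos):
            g = regular_pool[j]
            gi = config.n_tfs + j
            lfc = config.dd_de_log2fc * (1 if i % 2 == 0 else -1)
            state_log2[config.n_states - 1, gi] = (
                state_log2[config.n_states - 2, gi] + lfc)
            dd_rows.append(dict(gene=g, state_a=sa, state_b=sb, category="DE"))
        extra_dropout = np.zeros((n_cells, n_genes), dtype=np.float32)
        for j in dz_pos:
            g = regular_pool[j]
            gi = config.n_tfs + j
            state_log2[config.n_states - 1, gi] = state_log2[
                config.n_states - 2, gi]
            extra_dropout[sb_cells, gi] = config.dd_dz_extra_dropout
            dd_rows.append(dict(gene=g, state_a=sa, state_b=sb, category="DZ"))
        dm_boost = np.zeros((n_cells, n_genes), dtype=np.float32)
        half = rng.random(n_cells) < 0.5
        for j in dm_pos:
            g = regular_pool[j]
            gi = config.n_tfs + j
            state_log2[config.n_states - 1, gi] = state_log2[
                config.n_states - 2, gi]
            dm_boost[sb_cells & half, gi] = config.dd_dm_log2_shift
            dd_rows.append(dict(gene=g, state_a=sa, state_b=sb, category="DM"))
    dd_genes = pd.DataFrame(dd_rows, columns=["gene", "state_a", "state_b",
                                              "category"])

    donor_factor = rng.lognormal(0.0, config.donor_effect_sd,
                                 size=(config.n_donors, n_genes))

    rel = base[None, :] * np.exp2(state_log2[state_idx, :])
    if dm_boost is not None:
        rel = rel * np.exp2(dm_boost)
    cyc_cells = cycling_state[state_idx]
    if cycle_pos:
        cyc_cols = config.n_tfs + np.asarray(cycle_pos)
        rel[np.ix_(cyc_cells, cyc_cols)] *= 2.0 ** config.cycle_effect
    for r, reg in enumerate(planted):
        tf_col = r
        rel[:, tf_col] *= np.exp2(config.regulon_effect * activities[r])
        sgn = 1.0 if reg.sign == "+" else -1.0
        tgt_cols = np.array([genes.index(t) for t in reg.targets])
        rel[:, tgt_cols] *= np.exp2(
            sgn * config.regulon_effect * activities[r])[:, None]
    rel = rel * donor_factor[donor_idx, :]

    # QC outliers: high-mito cells and huge-library cells
    all_cells = rng.permutation(n_cells)
    mito_out = all_cells[:min(config.n_outlier_mito, n_cells)]
    lib_out = all_cells[config.n_outlier_mito:
                        config.n_outlier_mito + config.n_outlier_libsize]
    mito_cols = np.arange(config.n_tfs + len(regular), n_genes)
    if len(mito_out) and len(mito_cols):
        rel[np.ix_(mito_out, mito_cols)] *= 6.0

    libsize = rng.lognormal(config.libsize_mu, config.libsize_sigma,
                            size=n_cells)
    libsize[lib_out] *= 15.0
    mu = rel / rel.sum(axis=1, keepdims=True) * libsize[:, None]

    phi = 10.0 ** rng.uniform(np.log10(0.1), np.log10(2.0), size=n_genes)
    lam = rng.gamma(1.0 / phi[None, :], mu * phi[None, :])
    counts = rng.poisson(lam).astype(np.int32)

    p_drop = _dropout_probability(mu, config.dropout_midpoint,
                                  config.dropout_slope)
    if extra_dropout is not None:
        p_drop = 1.0 - (1.0 - p_drop) * (1.0 - extra_dropout)
    if np.any(p_drop > 0):
        counts[rng.random(counts.shape) < p_drop] = 0

    phase = np.where(cyc_cells,
                     np.where(rng.random(n_cells) < 0.5, "S", "G2M"), "G1")
    obs = pd.DataFrame({
        "donor": [f"donor{d + 1}" for d in donor_idx],
        "state": [states[s] for s in state_idx],
        "phase": phase,
        "total_umis": counts.sum(axis=1),
        "mito_frac": counts[:, mito_cols].sum(axis=1)
        / np.maximum(counts.sum(axis=1), 1),
        "is_planted_outlier": np.isin(np.arange(n_cells),
                                      np.concatenate([mito_out, lib_out])),
    }, index=pd.Index(barcodes, name="barcode"))
    var = pd.DataFrame({
        "is_tf": [g in set(tfs) for g in genes],
        "is_mito": [g.startswith("MT-") for g in genes],
    }, index=pd.Index(genes, name="gene"))
    adata = ad.AnnData(X=sp.csr_matrix(counts), obs=obs, var=var)

    truth = SyntheticTruth(
        planted_regulons=planted,
        tf_names=tfs,
        decoy_tfs=tfs[config.n_planted_regulons:],
        dd_genes=dd_genes,
        state_labels=obs["state"].copy(),
        outlier_cells=[barcodes[i] for i in np.sort(
            np.concatenate([mito_out, lib_out]))],
        cycle_genes=cycle_genes,
        gene_dispersion=pd.Series(phi, index=genes, name="dispersion"),
        expected_means=pd.DataFrame(mu, index=barcodes, columns=genes)
        if config.store_means else None,
    )
    return adata, truth


def simulate_motif_table(truth: SyntheticTruth,
                         config: SimulationConfig) -> pd.DataFrame:
    """TF->gene motif annotation: true edges kept with probability
    ``motif_tpr``, every other TF/gene pair admitted with ``motif_fpr``."""
    rng = np.random.default_rng([int(config.seed), 1])
    tfs, regular, mito = _gene_names(config)
    genes = tfs + regular + mito
    true_edges = {(r.tf, t) for r in truth.planted_regulons for t in r.targets}
    rows = []
    for tf in truth.tf_names:
        keep = rng.random(len(genes))
        for g, u in zip(genes, keep):
            if g == tf:
                continue
            if (tf, g) in true_edges:
                if u < config.motif_tpr:
                    rows.append((tf, g))
            elif u < config.motif_fpr:
                rows.append((tf, g))
    return pd.DataFrame(rows, columns=["tf", "gene"])


def gene_annotation(genes: list[str], start: int = 100_000,
                    spacing: int = 50_000) -> pd.DataFrame:
    """TSS table on one synthetic chromosome: genes on a fixed grid,
    strands alternating."""
    tss = start + spacing * np.arange(len(genes))
    strand = np.where(np.arange(len(genes)) % 2 == 0, "+", "-")
    return pd.DataFrame({"gene": genes, "chrom": "chrS", "tss": tss,
                         "strand": strand})


def chrom_length(annotation: pd.DataFrame, margin: int = 100_000) -> int:
    return int(annotation["tss"].max()) + margin


def simulate_peaks(truth: SyntheticTruth, annotation: pd.DataFrame,
                   config: SimulationConfig) -> pd.DataFrame:
    """BED-writable peaks: one near each true target's TSS with probability
    ``peak_tpr`` (width 200-600 bp, centre uniform within +-2 kb of the TSS),
    decoys near non-targets with probability ``peak_fpr``. Scores decrease in
    placement order; rank 1 is the best peak."""
    rng = np.random.default_rng([int(config.seed), 2])
    clen = chrom_length(annotation)
    if (annotation["tss"] < 0).any() or (annotation["tss"] >= clen).any():
        raise ValueError("TSS outside declared chromosome length")
    tss_by_gene = annotation.set_index("gene")["tss"]
    targets = sorted({t for r in truth.planted_regulons for t in r.targets})
    target_set = set(targets)
    others = [g for g in annotation["gene"] if g not in target_set]
    rows = []

    def place(gene: str) -> None:
        t = int(tss_by_gene[gene])
        width = int(rng.integers(200, 601))
        center = int(rng.integers(t - 2000, t + 2001))
        s = max(0, center - width // 2)
        rows.append(("chrS", s, s + width))

    for g in targets:
        if g in tss_by_gene.index and rng.random() < config.peak_tpr:
            place(g)
    for g in others:
        if rng.random() < config.peak_fpr:
            place(g)
    n = len(rows)
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["name"] = [f"peak{i + 1}" for i in range(n)]
    df["score"] = np.arange(n, 0, -1, dtype=float)
    df["strand"] = "."
    df["rank"] = np.arange(1, n + 1)
    return df


# ---------------------------------------------------------------------------
# dataset I/O (MTX triplet + TSVs + truth JSON)

def write_dataset(adata: ad.AnnData, truth: SyntheticTruth | None,
                  out_dir: str | Path) -> None:
    """Write a 10x-style triplet (genes x cells MTX, features, barcodes),
    cell metadata, and the planted truth as JSON. Round-trips losslessly
    through :func:`read_dataset`."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mat = sp.coo_matrix(adata.X.T)
    scipy.io.mmwrite(out / "matrix.mtx", mat, field="integer")
    feat = pd.DataFrame({
        "gene": adata.var_names,
        "is_tf": adata.var.get("is_tf", False),
        "is_mito": adata.var.get("is_mito",
                                 adata.var_names.str.startswith("MT-")),
    })
    feat.to_csv(out / "features.tsv", sep="\t", index=False)
    pd.Series(adata.obs_names, name="barcode").to_csv(
        out / "barcodes.tsv", sep="\t", index=False)
    meta = adata.obs.copy()
    meta.insert(0, "barcode", list(adata.obs_names))
    meta.to_csv(out / "cell_metadata.tsv", sep="\t", index=False)
    if truth is not None:
        payload = {
            "planted_regulons": [dataclasses.asdict(r)
                                 for r in truth.planted_regulons],
            "tf_names": truth.tf_names,
            "decoy_tfs": truth.decoy_tfs,
            "dd_genes": truth.dd_genes.to_dict(orient="records"),
            "outlier_cells": truth.outlier_cells,
            "cycle_genes": truth.cycle_genes,
            "gene_dispersion": {g: float(v) for g, v in
                                truth.gene_dispersion.items()},
        }
        with open(out / "truth.json", "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def read_dataset(in_dir: str | Path) -> tuple[ad.AnnData, SyntheticTruth | None]:
    """Read a dataset written by :func:`write_dataset` (or any 10x-style
    triplet with the same file names)."""
    d = Path(in_dir)
    mat = sp.csr_matrix(scipy.io.mmread(d / "matrix.mtx").T)
    feat = pd.read_csv(d / "features.tsv", sep="\t")
    barcodes = pd.read_csv(d / "barcodes.tsv", sep="\t")["barcode"]
    meta = pd.read_csv(d / "cell_metadata.tsv", sep="\t").set_index("barcode")
    meta = meta.loc[barcodes]
    var = feat.set_index("gene")
    adata = ad.AnnData(X=mat.astype(np.int32), obs=meta, var=var)
    truth = None
    tpath = d / "truth.json"
    if tpath.exists():
        with open(tpath) as fh:
            payload = json.load(fh)
        truth = SyntheticTruth(
            planted_regulons=[PlantedRegulon(**r)
                              for r in payload["planted_regulons"]],
            tf_names=payload["tf_names"],
            decoy_tfs=payload["decoy_tfs"],
            dd_genes=pd.DataFrame(payload["dd_genes"],
                                  columns=["gene", "state_a", "state_b",
                                           "category"]),
            state_labels=meta["state"] if "state" in meta else pd.Series(dtype=object),
            outlier_cells=payload["outlier_cells"],
            cycle_genes=payload["cycle_genes"],
            gene_dispersion=pd.Series(payload["gene_dispersion"],
                                      name="dispersion"),
        )
    return adata, truth
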