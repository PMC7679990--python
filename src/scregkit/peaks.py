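"""Peak handling and peak-to-gene regulatory-domain association.

Peaks (BED6 / narrowPeak) are pooled, merged, ranked by enrichment and
optionally cleared of TSS-overlapping intervals. Genes get a
basal-plus-extension regulatory domain (a strand-aware basal window
around the TSS, extended toward the neighbouring genes' basal domains up
to a maximum distance); a peak is associated with every gene whose
domain contains the peak midpoint. Regulon target sets are validated
against the per-gene peak summaries.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .regulons import Regulon

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]
NARROWPEAK_EXTRA = ["signalValue", "pValue", "qValue", "peak"]


def _rank_peaks(df: pd.DataFrame) -> pd.DataFrame:
    """Rank 1 = best score; ties broken by genomic position."""
    df = df.sort_values(["score", "chrom", "start"],
                        ascending=[False, True, True],
                        kind="mergesort").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def read_peaks(path, fmt: str | None = None, score_column: int | None = None
               ) -> pd.DataFrame:
    """Read BED6 or narrowPeak into a ranked peak table.

    Intervals are 0-based half-open. The enrichment score comes from
    column 5 (BED) or column 7, signalValue (narrowPeak); ``score_column``
    (1-based) overrides. Malformed lines raise with their line number.
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed line {ln}: fewer than 3 fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as e:
                raise ValueError(f"malformed line {ln}: {e}") from None
            if not 0 <= start < end:
                raise ValueError(
                    f"malformed line {ln}: require 0 <= start < end")
            rows.append(parts)
    if not rows:
        return pd.DataFrame(columns=BED_COLUMNS + ["rank"])
    width = max(len(r) for r in rows)
    if fmt is None:
        fmt = "narrowPeak" if width >= 10 else "BED"
    if score_column is None:
        score_column = 7 if fmt == "narrowPeak" else 5
    out = []
    for ln, parts in enumerate(rows, start=1):
        if len(parts) < score_column:
            raise ValueError(
                f"malformed line: missing score column {score_column}")
        out.append({
            "chrom": parts[0],
            "start": int(parts[1]),
            "end": int(parts[2]),
            "name": parts[3] if len(parts) > 3 else f"peak{ln}",
            "score": float(parts[score_column - 1]),
            "strand": parts[5] if len(parts) > 5 else ".",
        })
    return _rank_peaks(pd.DataFrame(out))


def write_peaks(peaks: pd.DataFrame, path) -> None:
    """Write BED6 (scores formatted with repr-stable %g)."""
    with open(path, "w") as fh:
        for _, row in peaks.iterrows():
            fh.write(f"{row['chrom']}\t{int(row['start'])}\t{int(row['end'])}"
                     f"\t{row.get('name', '.')}\t{row['score']:g}"
                     f"\t{row.get('strand', '.')}\n")


def pool_merge_peaks(peaksets) -> pd.DataFrame:
    """Union of intervals; overlapping or bookended intervals merge, the
    merged score is the maximum of the members. Result is re-ranked."""
    frames = [p for p in peaksets if len(p)]
    if not frames:
        return pd.DataFrame(columns=BED_COLUMNS + ["rank"])
    allp = pd.concat(frames, ignore_index=True).sort_values(
        ["chrom", "start", "end"], kind="mergesort")
    merged = []
    cur = None
    for row in allp.itertuples(index=False):
        if cur is not None and row.chrom == cur["chrom"] \
                and row.start <= cur["end"]:
            cur["end"] = max(cur["end"], row.end)
            cur["score"] = max(cur["score"], row.score)
        else:
            if cur is not None:
                merged.append(cur)
            cur = {"chrom": row.chrom, "start": int(row.start),
                   "end": int(row.end), "score": float(row.score)}
    if cur is not None:
        merged.append(cur)
    df = pd.DataFrame(merged)
    df["name"] = [f"merged{i + 1}" for i in range(len(df))]
    df["strand"] = "."
    return _rank_peaks(df[BED_COLUMNS])


def select_top_peaks(peaks: pd.DataFrame, n: int = 10_000) -> pd.DataFrame:
    """Top n peaks by score (ties by genomic position), re-ranked 1..n."""
    return _rank_peaks(peaks.copy()).head(n).reset_index(drop=True)


def filter_tss_overlap(peaks: pd.DataFrame, annotation: pd.DataFrame,
                       tss_window: int = 0) -> pd.DataFrame:
    """Remove peaks overlapping a TSS window.

    The window is [tss - w, tss + w) for w > 0; the default w = 0 means the
    single TSS base [tss, tss + 1). Half-open logic throughout: a peak
    ending exactly at the TSS does not overlap it.
    """
    if len(peaks) == 0:
        return peaks.copy()
    keep = np.ones(len(peaks), dtype=bool)
    for chrom, ann in annotation.groupby("chrom"):
        tss = ann["tss"].to_numpy()
        if tss_window > 0:
            win = np.column_stack([tss - tss_window, tss + tss_window])
        else:
            win = np.column_stack([tss, tss + 1])
        sel = peaks["chrom"] == chrom
        for i in np.where(sel)[0]:
            s, e = peaks["start"].iloc[i], peaks["end"].iloc[i]
            if np.any((s < win[:, 1]) & (e > win[:, 0])):
                keep[i] = False
    return peaks[keep].reset_index(drop=True)


def build_domains(annotation: pd.DataFrame, basal_up: int = 5000,
                  basal_down: int = 1000, max_ext: int = 1_000_000
                  ) -> pd.DataFrame:
    """Basal-plus-extension regulatory domains.

    Basal: ``basal_up`` upstream / ``basal_down`` downstream of the TSS in
    gene orientation ([tss-5000, tss+1000) on +, mirrored on -). Each basal
    edge extends outward to the nearest other gene's basal edge or by
    ``max_ext``, whichever is closer; the gene's own basal region is never
    truncated. Coordinates are clipped at 0.
    """
    if annotation["gene"].duplicated().any():
        raise ValueError("duplicate gene ids in annotation")
    out = annotation.copy().reset_index(drop=True)
    plus = out["strand"] == "+"
    out["basal_start"] = np.where(plus, out["tss"] - basal_up,
                                  out["tss"] - basal_down)
    out["basal_end"] = np.where(plus, out["tss"] + basal_down,
                                out["tss"] + basal_up)
    out["basal_start"] = out["basal_start"].clip(lower=0)
    dom_start = np.empty(len(out), dtype=np.int64)
    dom_end = np.empty(len(out), dtype=np.int64)
    for chrom, idx in out.groupby("chrom").groups.items():
        idx = np.asarray(idx)
        bs = out.loc[idx, "basal_start"].to_numpy()
        be = out.loc[idx, "basal_end"].to_numpy()
        ends_sorted = np.sort(be)
        starts_sorted = np.sort(bs)
        for j, gi in enumerate(idx):
            lo = bs[j] - max_ext
            pos = np.searchsorted(ends_sorted, bs[j], side="right") - 1
            if pos >= 0:
                lo = max(lo, ends_sorted[pos])
            dom_start[gi] = max(0, min(bs[j], lo))
            hi = be[j] + max_ext
            pos = np.searchsorted(starts_sorted, be[j], side="left")
            if pos < len(starts_sorted):
                hi = min(hi, starts_sorted[pos])
            dom_end[gi] = max(be[j], hi)
    out["dom_start"] = dom_start
    out["dom_end"] = dom_end
    return out


def associate_peaks(peaks: pd.DataFrame, domains: pd.DataFrame,
                    use_midpoint: bool = True) -> pd.DataFrame:
    """Associate each peak with every gene whose regulatory domain contains
    its midpoint (or overlaps the whole interval when ``use_midpoint`` is
    False). Returns one row per gene: peak count, ranks, and signed
    midpoint-to-TSS distances (positive downstream of the TSS in gene
    orientation)."""
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in domains.groupby("chrom"):
        t = IntervalTree()
        for row in grp.itertuples(index=False):
            if row.dom_start < row.dom_end:
                t[row.dom_start:row.dom_end] = row
        trees[chrom] = t
    hits: dict[str, dict] = {
        g: {"ranks": [], "distances": []} for g in domains["gene"]}
    for p in peaks.itertuples(index=False):
        tree = trees.get(p.chrom)
        if tree is None:
            continue
        mid = (int(p.start) + int(p.end)) // 2
        found = tree[mid] if use_midpoint else tree[int(p.start):int(p.end)]
        for iv in found:
            g = iv.data
            d = mid - g.tss
            if g.strand == "-":
                d = -d
            hits[g.gene]["ranks"].append(int(p.rank))
            hits[g.gene]["distances"].append(int(d))
    rows = []
    for g in domains["gene"]:
        ranks = sorted(hits[g]["ranks"])
        rows.append({"gene": g, "n_peaks": len(ranks), "peak_ranks": ranks,
                     "distances": sorted(hits[g]["distances"])})
    return pd.DataFrame(rows)


def validate_regulon(regulon: Regulon, associations: pd.DataFrame,
                     n_iter: int = 10) -> dict:
    """Summarize peak support of a regulon's targets.

    Returns the fraction of targets with at least one associated peak, the
    same fraction stratified by Npred (1..n_iter), and the mean best peak
    rank over supported targets. Targets missing from the annotation count
    in the denominator.
    """
    if not regulon.targets:
        raise ValueError("empty regulon")
    assoc = associations.set_index("gene")
    total = len(regulon.targets)
    with_peak = 0
    best_ranks = []
    strata: dict[int, list[bool]] = {i: [] for i in range(1, n_iter + 1)}
    missing = 0
    for gene, npred in regulon.targets.items():
        if gene in assoc.index:
            n = int(assoc.loc[gene, "n_peaks"])
            supported = n > 0
            if supported:
                with_peak += 1
                best_ranks.append(min(assoc.loc[gene, "peak_ranks"]))
        else:
            missing += 1
            supported = False
        strata.setdefault(int(npred), []).append(supported)
    frac_by_npred = {k: (float(np.mean(v)) if v else np.nan)
                     for k, v in sorted(strata.items())}
    return {
        "n_targets": total,
        "n_missing_annotation": missing,
        "frac_with_peak": with_peak / total,
        "frac_by_npred": frac_by_npred,
        "mean_best_rank": float(np.mean(best_ranks)) if best_ranks else np.nan,
    }
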