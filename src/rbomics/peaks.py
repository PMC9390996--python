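"""ChIP-seq peak integration: replicate intersection, peak-to-gene
assignment, TSS-distance binning, feature annotation, differential-expression
integration and super-enhancer overlap.

Peaks and super-enhancers are BED-style intervals (0-based half-open); TSS
positions are 1-based. Signed peak-gene distance is measured from the TSS to
the peak center and flipped on the minus strand so that negative always
means upstream of the gene. Distance bins follow the promoter +/- 3 kb
convention: |d| <= 3 kb promoter, 3-10 kb, 10-100 kb (presumed enhancers)
and > 100 kb.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BIN_PROMOTER = "promoter_3kb"
BIN_MID = "mid_3to10kb"
BIN_DISTAL = "distal_10to100kb"
BIN_FAR = "far_over100kb"
BINS = (BIN_PROMOTER, BIN_MID, BIN_DISTAL, BIN_FAR)

FEATURE_PRIORITY = ("promoter", "utr5", "utr3", "exon", "intron", "intergenic")


def distance_bin(distance: float, promoter: int = 3000, mid: int = 10_000,
                 distal: int = 100_000) -> str:
    d = abs(distance)
    if d <= promoter:
        return BIN_PROMOTER
    if d <= mid:
        return BIN_MID
    if d <= distal:
        return BIN_DISTAL
    return BIN_FAR


def _check_sorted(peaks: pd.DataFrame, label: str) -> pd.DataFrame:
    if (peaks["start"] >= peaks["end"]).any():
        raise ValueError(f"{label}: intervals must satisfy start < end")
    ordered = peaks.sort_values(["chrom", "start", "end"], kind="stable")
    return ordered.reset_index(drop=True)


def high_confidence_peaks(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Merge two replicate peak sets into high-confidence shared peaks.

    Peaks from both replicates are clustered by transitive >= 1 bp overlap;
    every cluster containing at least one peak from each replicate yields
    one output interval spanning the cluster. Symmetric in its arguments.
    """
    a = _check_sorted(a, "replicate A")
    b = _check_sorted(b, "replicate B")
    merged = pd.concat([a[["chrom", "start", "end"]].assign(src=0),
                        b[["chrom", "start", "end"]].assign(src=1)],
                       ignore_index=True)
    merged = merged.sort_values(["chrom", "start", "end"], kind="stable")

    out = []
    cur = None  # [chrom, start, end, has_a, has_b]
    for r in merged.itertuples():
        if cur is not None and r.chrom == cur[0] and r.start < cur[2]:
            cur[2] = max(cur[2], r.end)
            cur[3 + r.src] = True
        else:
            if cur is not None and cur[3] and cur[4]:
                out.append(cur[:3])
            cur = [r.chrom, r.start, r.end, r.src == 0, r.src == 1]
    if cur is not None and cur[3] and cur[4]:
        out.append(cur[:3])
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def peak_center(peaks: pd.DataFrame) -> np.ndarray:
    return ((peaks["start"].to_numpy() + peaks["end"].to_numpy()) // 2)


def assign_peaks_to_genes(peaks: pd.DataFrame, genes: pd.DataFrame,
                          ) -> pd.DataFrame:
    """Link each peak to its nearest gene by center-to-TSS distance.

    ``genes`` needs gene_id, chrom, tss (1-based), strand. Ties in |distance|
    break by lexicographically smallest gene_id. Peaks on chromosomes without
    genes get a null gene_id and the far bin. Returns one row per peak:
    chrom, start, end, gene_id, signed_distance, bin.
    """
    if genes.empty:
        raise ValueError("gene annotation is empty")
    by_chrom: dict[str, tuple[np.ndarray, list[list[tuple[str, str]]]]] = {}
    for chrom, grp in genes.groupby("chrom"):
        pos_map: dict[int, list[tuple[str, str]]] = {}
        for g in grp.itertuples():
            pos_map.setdefault(int(g.tss) - 1, []).append((str(g.gene_id), str(g.strand)))
        positions = np.array(sorted(pos_map), dtype=np.int64)
        by_chrom[chrom] = (positions, [sorted(pos_map[p]) for p in positions])

    centers = peak_center(peaks)
    rows = []
    for (r, center) in zip(peaks.itertuples(), centers):
        entry = by_chrom.get(r.chrom)
        if entry is None:
            rows.append((r.chrom, r.start, r.end, None, np.nan, BIN_FAR))
            continue
        positions, genes_at = entry
        i = int(np.searchsorted(positions, center))
        cands = [j for j in (i - 1, i) if 0 <= j < len(positions)]
        best = min(abs(int(positions[j]) - center) for j in cands)
        choices = []
        for j in cands:
            if abs(int(positions[j]) - center) == best:
                choices.extend((gid, strand, int(positions[j]))
                               for gid, strand in genes_at[j])
        gid, strand, tss0 = min(choices)
        signed = center - tss0 if strand == "+" else tss0 - center
        rows.append((r.chrom, r.start, r.end, gid, signed, distance_bin(signed)))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "gene_id", "signed_distance", "bin"])


def annotate_peak_features(peaks: pd.DataFrame, genes: pd.DataFrame,
                           structures: pd.DataFrame | None = None,
                           promoter_window: int = 3000) -> pd.Series:
    """Classify each peak center into a genomic feature.

    Priority: promoter > utr5 > utr3 > exon > intron > intergenic, tested at
    the peak center. Promoters are TSS +/- ``promoter_window``; the other
    classes come from ``structures`` (chrom, start, end, feature; 0-based
    half-open).
    """
    tss0 = genes["tss"].to_numpy(dtype=np.int64) - 1
    promoters = pd.DataFrame({
        "chrom": genes["chrom"],
        "start": np.maximum(tss0 - promoter_window, 0),
        "end": tss0 + promoter_window + 1,
        "feature": "promoter",
    })
    frames = [promoters]
    if structures is not None and not structures.empty:
        frames.append(structures[["chrom", "start", "end", "feature"]])
    annot = pd.concat(frames, ignore_index=True)

    prio = {f: i for i, f in enumerate(FEATURE_PRIORITY)}
    centers = peak_center(peaks)
    labels = []
    by_chrom = {c: g for c, g in annot.groupby("chrom")}
    for r, center in zip(peaks.itertuples(), centers):
        grp = by_chrom.get(r.chrom)
        label = "intergenic"
        if grp is not None:
            hit = grp[(grp["start"] <= center) & (center < grp["end"])]
            if not hit.empty:
                label = min(hit["feature"], key=lambda f: prio[f])
        labels.append(label)
    return pd.Series(labels, index=peaks.index, name="feature")


@dataclass
class IntegrationSummary:
    n_peaks: int
    n_de_linked_peaks: int
    n_de_genes_with_peak: int
    n_up_genes: int
    n_down_genes: int
    n_up_peaks: int
    n_down_peaks: int
    bin_counts: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "n_peaks": self.n_peaks,
            "n_de_linked_peaks": self.n_de_linked_peaks,
            "n_de_genes_with_peak": self.n_de_genes_with_peak,
            "n_up_genes": self.n_up_genes,
            "n_down_genes": self.n_down_genes,
            "n_up_peaks": self.n_up_peaks,
            "n_down_peaks": self.n_down_peaks,
            "bin_counts": dict(self.bin_counts),
        }


def integrate_with_de(links: pd.DataFrame, de: pd.DataFrame,
                      fdr_cut: float = 0.05
                      ) -> tuple[pd.DataFrame, IntegrationSummary]:
    """Label peak-gene links by the differential expression of their gene.

    ``de`` needs gene_id, log_fold_change, fdr (unique gene_id). Links whose
    gene is significantly up/down (fdr < fdr_cut) get de_direction up/down;
    everything else none. The summary counts DE-linked peaks and genes per
    direction and the TSS-distance bin distribution of DE-linked peaks.
    """
    if de["gene_id"].duplicated().any():
        raise ValueError("duplicate gene_id in DE table")
    de_ix = de.set_index("gene_id")
    sig = de_ix[de_ix["fdr"] < fdr_cut]

    def direction(gid) -> str:
        if gid is None or gid not in sig.index:
            return "none"
        return "up" if sig.loc[gid, "log_fold_change"] > 0 else "down"

    out = links.copy()
    out["de_direction"] = [direction(g) for g in links["gene_id"]]

    linked = out[out["de_direction"] != "none"]
    up = linked[linked["de_direction"] == "up"]
    down = linked[linked["de_direction"] == "down"]
    summary = IntegrationSummary(
        n_peaks=len(out),
        n_de_linked_peaks=len(linked),
        n_de_genes_with_peak=linked["gene_id"].nunique(),
        n_up_genes=up["gene_id"].nunique(),
        n_down_genes=down["gene_id"].nunique(),
        n_up_peaks=len(up),
        n_down_peaks=len(down),
        bin_counts={b: int((linked["bin"] == b).sum()) for b in BINS},
    )
    return out, summary


def super_enhancer_overlap(peaks: pd.DataFrame, se_regions: pd.DataFrame
                           ) -> tuple[int, int, float]:
    """Count super-enhancer intervals containing >= 1 bp of >= 1 peak.

    Returns (n_se_with_peak, n_se_total, percent to one decimal).
    """
    from .report import percentage

    n_total = len(se_regions)
    if n_total == 0:
        return 0, 0, 0.0
    n_hit = 0
    by_chrom = {c: g.sort_values("start") for c, g in peaks.groupby("chrom")}
    for se in se_regions.itertuples():
        grp = by_chrom.get(se.chrom)
        if grp is None:
            continue
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        if ((starts < se.end) & (ends > se.start)).any():
            n_hit += 1
    return n_hit, n_total, percentage(n_hit, n_total)
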