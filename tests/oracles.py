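"""Independent brute-force reference implementations used as test oracles.

Everything here is written naively (per-row loops, all-pairs scans,
closed-form sums) and deliberately shares no code with the package.
"""

from __future__ import annotations

import math

import numpy as np


def _unknown(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def naive_failed_rules(row: dict, pon_counts: dict, shared_keys: set) -> list[str]:
    """Rule-by-rule re-derivation of the filter cascade for one variant."""
    failed = []
    key = (row["chrom"], row["pos"], row["ref"], row["alt"])
    if pon_counts.get(key, 0) >= 2:
        failed.append("panel_of_normals")
    alt = row["tumor_alt_reads"]
    blood = row["blood_alt_reads"]
    read_fail = alt < 3
    if not _unknown(blood) and alt < 8 and blood > 1:
        read_fail = True
    if read_fail:
        failed.append("read_support")
    if row["tumor_vaf"] < 0.05:
        failed.append("vaf")
    pop_fail = False
    for f in ("pop_maf_1000g", "pop_maf_esp"):
        if not _unknown(row[f]) and row[f] >= 0.01:
            pop_fail = True
    if pop_fail:
        failed.append("population")
    if row["in_dbsnp"]:
        maf = row["dbsnp_pop_maf"]
        exc1 = _unknown(maf) or maf < 0.01
        single = row["dbsnp_single_mapping"]
        exc2 = (not _unknown(single)) and bool(single)
        exc3 = bool(row["dbsnp_clinical_tag"])
        if not (exc1 or exc2 or exc3):
            failed.append("dbsnp")
    if key in shared_keys:
        failed.append("shared_indel")
    return failed


def naive_shared_indel_keys(rows: list[dict]) -> set:
    """Cohort-wide shared-indel germline heuristic, enumerated naively."""
    indel_types = {"insertion", "deletion", "MNV_nonframeshift"}
    by_key: dict[tuple, list[dict]] = {}
    for r in rows:
        if r["variant_type"] in indel_types:
            by_key.setdefault(
                (r["chrom"], r["pos"], r["ref"], r["alt"]), []).append(r)
    shared = set()
    for key, occ in by_key.items():
        unmatched = {r["sample_id"] for r in occ if not r["matched_normal_available"]}
        matched = {r["sample_id"] for r in occ if r["matched_normal_available"]}
        if len(unmatched) >= 2 and len(matched) == 0:
            shared.add(key)
    return shared


def naive_high_confidence(a: list[tuple], b: list[tuple]) -> list[tuple]:
    """All-pairs union-find overlap clustering of two interval sets.

    Intervals are (chrom, start, end) half-open; returns the union span of
    every connected component containing members of both sets.
    """
    items = [(iv, 0) for iv in a] + [(iv, 1) for iv in b]
    parent = list(range(len(items)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            (ci, si, ei), _ = items[i]
            (cj, sj, ej), _ = items[j]
            if ci == cj and si < ej and sj < ei:
                parent[find(i)] = find(j)

    comps: dict[int, list[int]] = {}
    for i in range(len(items)):
        comps.setdefault(find(i), []).append(i)
    out = []
    for members in comps.values():
        srcs = {items[i][1] for i in members}
        if srcs == {0, 1}:
            chrom = items[members[0]][0][0]
            out.append((chrom,
                        min(items[i][0][1] for i in members),
                        max(items[i][0][2] for i in members)))
    return sorted(out)


def naive_nearest_gene(center: int, genes: list[tuple]) -> tuple:
    """genes: (gene_id, tss0, strand) on one chromosome. Returns
    (gene_id, signed_distance) with lexicographic tie-break on gene_id."""
    best = None
    for gene_id, tss0, strand in sorted(genes):
        d = abs(center - tss0)
        if best is None or d < best[0] or (d == best[0] and gene_id < best[1]):
            signed = center - tss0 if strand == "+" else tss0 - center
            best = (d, gene_id, signed)
    return best[1], best[2]


def naive_bin(distance: float) -> str:
    d = abs(distance)
    if d <= 3000:
        return "promoter_3kb"
    if d <= 10_000:
        return "mid_3to10kb"
    if d <= 100_000:
        return "distal_10to100kb"
    return "far_over100kb"


def naive_feature(center: int, intervals: list[tuple]) -> str:
    """intervals: (start, end, feature) on the peak's chromosome."""
    order = ["promoter", "utr5", "utr3", "exon", "intron", "intergenic"]
    hits = {f for s, e, f in intervals if s <= center < e}
    for f in order:
        if f in hits:
            return f
    return "intergenic"


_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def naive_consensus_scan(seq: str, pattern: str) -> list[tuple]:
    """Per-position double-stranded IUPAC match; N in seq never matches."""
    def matches(window: str, pat: str) -> bool:
        return all(b in _IUPAC[p] and b != "N" for b, p in zip(window, pat))

    # reverse-complement of an IUPAC pattern needs code-level complementing
    comp_code = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")
    rc = pattern.translate(comp_code)[::-1]
    hits = []
    for i in range(len(seq) - len(pattern) + 1):
        w = seq[i:i + len(pattern)]
        if "N" in w:
            continue
        if matches(w, pattern):
            hits.append((i, "+"))
        if matches(w, rc):
            hits.append((i, "-"))
    return sorted(hits)


def naive_pwm_scan(seq: str, pwm: np.ndarray, threshold_frac: float,
                   background=None) -> list[tuple]:
    bg = np.full(4, 0.25) if background is None else np.asarray(background)
    lo = np.log2((pwm + 1e-6) / (bg[:, None] + 1e-6))
    cutoff = threshold_frac * lo.max(axis=0).sum()
    L = pwm.shape[1]
    ix = {"A": 0, "C": 1, "G": 2, "T": 3}
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    hits = []
    for i in range(len(seq) - L + 1):
        w = seq[i:i + L]
        if "N" in w:
            continue
        fwd = sum(lo[ix[b], j] for j, b in enumerate(w))
        rc = "".join(comp[b] for b in reversed(w))
        rev = sum(lo[ix[b], j] for j, b in enumerate(rc))
        if fwd >= cutoff:
            hits.append((i, "+"))
        if rev >= cutoff:
            hits.append((i, "-"))
    return sorted(hits)


def naive_hypergeom_sf(k: int, M: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(M population, K successes, N draws)."""
    total = 0.0
    for x in range(k, min(K, N) + 1):
        total += math.comb(K, x) * math.comb(M - K, N - x)
    return total / math.comb(M, N)
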