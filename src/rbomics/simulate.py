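"""Synthetic data generators with ground-truth labels.

Every input the pipeline consumes can be generated here with known truth, so
each downstream stage is testable without controlled-access data:

* a tumor cohort of variant calls (somatic / germline / artifact classes
  with read counts drawn from a Binomial(depth, VAF) model, matched-blood
  evidence, population and dbSNP annotation, predictor calls) plus a panel
  of normals;
* per-sample arm-tiled copy-ratio segments with planted gains/losses and
  optional planted isodisomy;
* a peak/gene/differential-expression fixture with peaks planted at known
  signed distances from known TSSs;
* a sparse single-cell count matrix in which each planted low-quality cell
  violates exactly one named QC rule.

Defaults mirror a retinoblastoma-style exome cohort: ~100 tumors, ~90%
with matched blood, a panel of 117 normals, tens of called variants per
sample surviving the caller, somatic VAFs centered on 0.35, heterozygous
germline VAFs near 0.5 and low-fraction artifacts near 0.03 (so the 5%
allele-fraction cutoff is exercised on both sides). All generators are
deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._arms import ARM_TABLE, _HG19_CHROMS
from .variants import PanelOfNormals

_BASES = np.array(list("ACGT"))
_AUTOSOMES = [f"chr{i}" for i in range(1, 23)]


@dataclass
class VAFModel:
    """Beta parameters of the per-class allele-fraction distributions."""

    somatic_a: float = 3.5
    somatic_b: float = 6.5       # mean 0.35
    germline_a: float = 40.0
    germline_b: float = 40.0     # tight around 0.5 (heterozygous)
    artifact_a: float = 0.6
    artifact_b: float = 19.4     # mean 0.03


@dataclass
class DepthModel:
    tumor_mean: float = 150.0
    blood_mean: float = 100.0


@dataclass
class CohortSimConfig:
    n_tumors: int = 103
    frac_matched: float = 92 / 103
    n_panel_normals: int = 117
    somatic_rate: float = 15.0    # expected calls per tumor per class
    germline_rate: float = 30.0
    artifact_rate: float = 10.0
    vaf_model: VAFModel = field(default_factory=VAFModel)
    depth_model: DepthModel = field(default_factory=DepthModel)
    predictor_error: float = 0.1
    predictor_missing_rate: float = 0.05
    possibly_damaging_frac: float = 0.3
    germline_panel_share: float = 0.5   # P(germline variant seen in >= 2 normals)
    artifact_panel_share: float = 0.3   # P(recurrent artifact in >= 2 normals)
    n_shared_indels: int = 3            # germline indels shared across unmatched tumors
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("somatic_rate", "germline_rate", "artifact_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("frac_matched", "predictor_error", "predictor_missing_rate",
                     "possibly_damaging_frac", "germline_panel_share",
                     "artifact_panel_share"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_tumors < 0 or self.n_panel_normals < 0:
            raise ValueError("counts must be >= 0")


_TYPE_PROBS = (("SNV", 0.80), ("insertion", 0.08), ("deletion", 0.08),
               ("MNV_nonframeshift", 0.02), ("MNV_other", 0.02))
_CLASS_PROBS = (("nonsynonymous_exonic", 0.50), ("synonymous", 0.15),
                ("nonexonic", 0.25), ("splicing", 0.10))


def _random_site(rng: np.random.Generator) -> tuple[str, int]:
    chrom = _AUTOSOMES[rng.integers(0, len(_AUTOSOMES))]
    return chrom, int(rng.integers(1, _HG19_CHROMS[chrom][0]))


def _random_alleles(rng: np.random.Generator, vtype: str) -> tuple[str, str]:
    if vtype == "SNV":
        ref = _BASES[rng.integers(0, 4)]
        alt = _BASES[(np.flatnonzero(_BASES != ref))[rng.integers(0, 3)]]
        return str(ref), str(alt)
    if vtype == "insertion":
        ref = str(_BASES[rng.integers(0, 4)])
        ins = "".join(_BASES[rng.integers(0, 4, size=rng.integers(1, 6))])
        return ref, ref + ins
    if vtype == "deletion":
        tail = "".join(_BASES[rng.integers(0, 4, size=rng.integers(1, 6))])
        ref = str(_BASES[rng.integers(0, 4)]) + tail
        return ref, ref[0]
    # multinucleotide substitution
    n = int(rng.integers(2, 4))
    ref = "".join(_BASES[rng.integers(0, 4, size=n)])
    alt = "".join(_BASES[rng.integers(0, 4, size=n)])
    while alt == ref:
        alt = "".join(_BASES[rng.integers(0, 4, size=n)])
    return ref, alt


def _choice(rng, pairs):
    names = [n for n, _ in pairs]
    probs = np.array([p for _, p in pairs])
    return names[rng.choice(len(names), p=probs / probs.sum())]


def _vaf(rng, vm: VAFModel, truth_class: str) -> float:
    a, b = {"somatic": (vm.somatic_a, vm.somatic_b),
            "germline": (vm.germline_a, vm.germline_b),
            "artifact": (vm.artifact_a, vm.artifact_b)}[truth_class]
    return float(np.clip(rng.beta(a, b), 1e-4, 1 - 1e-4))


def _predictor_calls(rng, truth_deleterious: bool, cfg: CohortSimConfig
                     ) -> tuple[str, str, str]:
    calls = []
    for predictor in ("polyphen", "fathmm", "metalr"):
        if rng.random() < cfg.predictor_missing_rate:
            calls.append("missing")
            continue
        damaging = truth_deleterious ^ (rng.random() < cfg.predictor_error)
        if predictor == "polyphen":
            if damaging:
                calls.append("possibly_damaging"
                             if rng.random() < cfg.possibly_damaging_frac
                             else "probably_damaging")
            else:
                calls.append("benign")
        else:
            calls.append("damaging" if damaging else "tolerated")
    return tuple(calls)


def simulate_variant_cohort(cfg: CohortSimConfig
                            ) -> tuple[pd.DataFrame, PanelOfNormals]:
    """Generate a labeled tumor variant cohort and its panel of normals.

    Returns (table, pon). The table holds every filter-cascade input column
    plus truth columns: truth_class in {somatic, germline, artifact},
    truth_deleterious, and the three predictor calls. Germline variants of
    matched samples show up in the blood reads; a configurable share of
    germline variants and recurrent artifacts is planted in the panel of
    normals; somatic variants never are.
    """
    rng = np.random.default_rng(cfg.seed)
    n_matched = int(round(cfg.frac_matched * cfg.n_tumors))
    samples = [f"T{i + 1:03d}" for i in range(cfg.n_tumors)]
    matched = {s: i < n_matched for i, s in enumerate(samples)}

    rows: list[dict] = []
    pon = PanelOfNormals()
    dm, vm = cfg.depth_model, cfg.vaf_model

    def emit(sample: str, truth_class: str, chrom: str, pos: int,
             ref: str, alt: str, vtype: str, fclass: str) -> None:
        vaf = _vaf(rng, vm, truth_class)
        depth = max(int(rng.poisson(dm.tumor_mean)), 10)
        alt_reads = int(rng.binomial(depth, vaf))
        if matched[sample]:
            blood_depth = max(int(rng.poisson(dm.blood_mean)), 10)
            blood_p = 0.5 if truth_class == "germline" else 0.002
            blood_alt = float(rng.binomial(blood_depth, blood_p))
        else:
            blood_alt = np.nan

        common = truth_class == "germline" and rng.random() < 0.5
        if common:
            maf = float(rng.uniform(0.01, 0.40))
            g1k, esp, in_dbsnp, dbsnp_maf = maf, maf, True, maf
        else:
            g1k = float(rng.uniform(0, 0.009)) if rng.random() < 0.3 else np.nan
            esp = float(rng.uniform(0, 0.009)) if rng.random() < 0.3 else np.nan
            in_dbsnp = bool(rng.random() < (0.3 if truth_class == "germline" else 0.03))
            dbsnp_maf = float(rng.uniform(0, 0.009)) if (in_dbsnp and rng.random() < 0.5) else np.nan

        if vtype == "SNV" and fclass != "splicing":
            truth_del = bool(rng.random() < (0.7 if truth_class == "somatic" else 0.3))
        else:
            truth_del = True
        polyphen, fathmm, metalr = _predictor_calls(rng, truth_del, cfg)

        rows.append({
            "sample_id": sample, "chrom": chrom, "pos": pos, "ref": ref,
            "alt": alt, "variant_type": vtype, "functional_class": fclass,
            "tumor_alt_reads": alt_reads, "tumor_ref_reads": depth - alt_reads,
            "blood_alt_reads": blood_alt,
            "tumor_vaf": alt_reads / depth,
            "pop_maf_1000g": g1k, "pop_maf_esp": esp,
            "in_dbsnp": in_dbsnp, "dbsnp_pop_maf": dbsnp_maf,
            "dbsnp_single_mapping": bool(rng.random() < 0.2) if in_dbsnp else False,
            "dbsnp_clinical_tag": bool(rng.random() < 0.02) if in_dbsnp else False,
            "matched_normal_available": matched[sample],
            "truth_class": truth_class,
            "truth_deleterious": truth_del,
            "polyphen": polyphen, "fathmm": fathmm, "metalr": metalr,
        })

    for sample in samples:
        for truth_class, rate in (("somatic", cfg.somatic_rate),
                                  ("germline", cfg.germline_rate),
                                  ("artifact", cfg.artifact_rate)):
            for _ in range(int(rng.poisson(rate))):
                vtype = _choice(rng, _TYPE_PROBS)
                fclass = _choice(rng, _CLASS_PROBS)
                chrom, pos = _random_site(rng)
                ref, alt = _random_alleles(rng, vtype)
                emit(sample, truth_class, chrom, pos, ref, alt, vtype, fclass)
                key = (chrom, pos, ref, alt)
                if truth_class == "germline" and rng.random() < cfg.germline_panel_share:
                    pon.add(key, 2 + int(rng.binomial(max(cfg.n_panel_normals - 2, 0), 0.05)))
                elif truth_class == "germline" and rng.random() < 0.5:
                    pon.add(key, 1)
                elif truth_class == "artifact" and rng.random() < cfg.artifact_panel_share:
                    pon.add(key, 2 + int(rng.binomial(max(cfg.n_panel_normals - 2, 0), 0.02)))

    # identical germline indels recurring across unmatched tumors (the
    # shared-indel heuristic's target); only plantable with >= 2 unmatched
    unmatched = [s for s in samples if not matched[s]]
    if len(unmatched) >= 2 and cfg.germline_rate > 0:
        for _ in range(cfg.n_shared_indels):
            vtype = "deletion" if rng.random() < 0.5 else "insertion"
            chrom, pos = _random_site(rng)
            ref, alt = _random_alleles(rng, vtype)
            k = int(rng.integers(2, len(unmatched) + 1))
            carriers = rng.choice(len(unmatched), size=k, replace=False)
            for ci in sorted(carriers):
                emit(unmatched[ci], "germline", chrom, pos, ref, alt,
                     vtype, "nonexonic")

    table = pd.DataFrame(rows)
    if not table.empty:
        table = table.drop_duplicates(
            subset=["sample_id", "chrom", "pos", "ref", "alt"], keep="first"
        ).reset_index(drop=True)
    else:
        table = pd.DataFrame(columns=[
            "sample_id", "chrom", "pos", "ref", "alt", "variant_type",
            "functional_class", "tumor_alt_reads", "tumor_ref_reads",
            "blood_alt_reads", "tumor_vaf", "pop_maf_1000g", "pop_maf_esp",
            "in_dbsnp", "dbsnp_pop_maf", "dbsnp_single_mapping",
            "dbsnp_clinical_tag", "matched_normal_available", "truth_class",
            "truth_deleterious", "polyphen", "fathmm", "metalr"])
    return table, pon


# ---------------------------------------------------------------------------
# arm segments


def simulate_arm_segments(n_samples: int,
                          planted_events: dict[tuple[str, str], float] | None = None,
                          noise_sd: float = 0.05,
                          seed: int = 0,
                          segments_per_arm: int = 6,
                          planted_isodisomy: set[tuple[str, str]] | None = None,
                          baf_noise_sd: float = 0.01,
                          arms: pd.DataFrame = ARM_TABLE,
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tile every arm of every sample with segments around planted means.

    ``planted_events`` maps (sample_id, arm) -> true mean log2 ratio; sample
    ids are S001..S{n}. Segment ratios are the planted mean (0 where none)
    plus Gaussian noise. ``planted_isodisomy`` arms get homozygous BAFs
    (near 0/1) instead of heterozygous ~0.5. Returns (segments, truth).
    """
    planted_events = planted_events or {}
    planted_isodisomy = planted_isodisomy or set()
    samples = [f"S{i + 1:03d}" for i in range(n_samples)]
    known = set(arms["arm"])
    for _, arm in list(planted_events) + list(planted_isodisomy):
        if arm not in known:
            raise KeyError(f"unknown arm: {arm!r}")
    bad = [s for s, _ in list(planted_events) + list(planted_isodisomy)
           if s not in samples]
    if bad:
        raise KeyError(f"unknown sample(s): {sorted(set(bad))}")

    rng = np.random.default_rng(seed)
    seg_rows, truth_rows = [], []
    for sample in samples:
        for arm_row in arms.itertuples():
            arm, chrom = arm_row.arm, arm_row.chrom
            mean = planted_events.get((sample, arm), 0.0)
            iso = (sample, arm) in planted_isodisomy
            widths = rng.dirichlet(np.full(segments_per_arm, 2.0))
            bounds = arm_row.start + np.round(
                np.cumsum(widths) * (arm_row.end - arm_row.start)).astype(np.int64)
            bounds[-1] = arm_row.end
            start = arm_row.start
            for end in bounds:
                if end <= start:
                    continue
                ratio = mean + (rng.normal(0, noise_sd) if noise_sd > 0 else 0.0)
                if iso:
                    baf = 0.02 if rng.random() < 0.5 else 0.98
                else:
                    baf = 0.5
                if baf_noise_sd > 0:
                    baf = float(np.clip(baf + rng.normal(0, baf_noise_sd), 0, 1))
                seg_rows.append((sample, chrom, int(start), int(end), ratio, baf))
                start = end
            truth_rows.append((sample, arm, mean, iso))
    segments = pd.DataFrame(
        seg_rows, columns=["sample_id", "chrom", "start", "end", "log2_ratio", "baf"])
    truth = pd.DataFrame(
        truth_rows, columns=["sample_id", "arm", "true_mean", "isodisomy"])
    return segments, truth


# ---------------------------------------------------------------------------
# integration fixture


@dataclass
class IntegrationFixture:
    peaks_a: pd.DataFrame
    peaks_b: pd.DataFrame
    genes: pd.DataFrame
    de: pd.DataFrame
    super_enhancers: pd.DataFrame
    truth: pd.DataFrame  # per peak of replicate A


_GENE_SPACING = 300_000
_PEAK_HALF_WIDTH = 100


def simulate_integration_fixture(n_genes: int, n_peaks: int,
                                 frac_promoter: float = 0.15,
                                 frac_de: float = 0.3,
                                 seed: int = 0,
                                 replicate_overlap: float = 0.8,
                                 frac_mid: float = 0.10,
                                 frac_distal: float = 0.50,
                                 n_se: int = 50,
                                 se_hit_frac: float = 0.5,
                                 ) -> IntegrationFixture:
    """Plant peaks at known signed distances from known TSSs.

    Genes are spaced 300 kb apart on one chromosome so the planted gene is
    always the unique nearest TSS (planted |distance| <= ~140 kb). Each peak
    draws a truth bin (promoter / 3-10 kb / 10-100 kb / >100 kb with the
    given fractions) and a sign. Replicate B repeats a ``replicate_overlap``
    fraction of replicate A's peaks (jittered but still overlapping) and
    scatters the rest in a gene desert. The DE table marks ``frac_de`` of
    genes significant with random direction; some super-enhancer intervals
    wrap planted peaks, the rest sit in a separate desert.
    """
    for name, v in (("frac_promoter", frac_promoter), ("frac_de", frac_de),
                    ("replicate_overlap", replicate_overlap)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must lie in [0, 1]")
    if n_genes == 0 and n_peaks > 0:
        raise ValueError("cannot place peaks without genes")
    if frac_promoter + frac_mid + frac_distal > 1 + 1e-9:
        raise ValueError("bin fractions must sum to <= 1")

    rng = np.random.default_rng(seed)
    chrom = "chr1"
    tss = 150_000 + np.arange(n_genes, dtype=np.int64) * _GENE_SPACING + 1
    strands = np.where(rng.random(n_genes) < 0.5, "+", "-")
    genes = pd.DataFrame({
        "gene_id": [f"G{i:04d}" for i in range(n_genes)],
        "chrom": chrom, "tss": tss, "strand": strands,
    })

    bin_names = ("promoter_3kb", "mid_3to10kb", "distal_10to100kb", "far_over100kb")
    probs = np.array([frac_promoter, frac_mid, frac_distal,
                      max(1 - frac_promoter - frac_mid - frac_distal, 0)])
    bin_ranges = {"promoter_3kb": (0, 3000), "mid_3to10kb": (3001, 10_000),
                  "distal_10to100kb": (10_001, 100_000),
                  "far_over100kb": (100_001, 140_000)}

    peak_rows, truth_rows = [], []
    for i in range(n_peaks):
        gi = int(rng.integers(0, n_genes))
        b = bin_names[rng.choice(4, p=probs / probs.sum())]
        lo, hi = bin_ranges[b]
        d = int(rng.integers(lo, hi + 1))
        if d > 0 and rng.random() < 0.5:
            d = -d
        tss0 = int(tss[gi]) - 1
        center = tss0 + d if strands[gi] == "+" else tss0 - d
        peak_rows.append((chrom, center - _PEAK_HALF_WIDTH, center + _PEAK_HALF_WIDTH))
        truth_rows.append((f"peak{i:05d}", genes["gene_id"].iloc[gi], b, d))

    peaks_a = pd.DataFrame(peak_rows, columns=["chrom", "start", "end"])
    truth = pd.DataFrame(
        truth_rows, columns=["peak_id", "gene_id", "bin", "signed_distance"])

    n_shared = int(round(replicate_overlap * n_peaks))
    shared_ix = np.sort(rng.choice(n_peaks, size=n_shared, replace=False)) \
        if n_peaks else np.array([], dtype=int)
    truth["in_both"] = np.isin(np.arange(n_peaks), shared_ix)
    desert = int(tss[-1]) + 1_000_000 if n_genes else 1_000_000
    b_rows = []
    for i in range(n_peaks):
        if i in set(shared_ix.tolist()):
            jitter = int(rng.integers(-_PEAK_HALF_WIDTH + 1, _PEAK_HALF_WIDTH))
            s = peak_rows[i][1] + jitter
            b_rows.append((chrom, s, s + 2 * _PEAK_HALF_WIDTH))
        else:
            s = desert + i * 1000
            b_rows.append((chrom, s, s + 2 * _PEAK_HALF_WIDTH))
    peaks_b = pd.DataFrame(b_rows, columns=["chrom", "start", "end"])

    n_de = int(round(frac_de * n_genes))
    de_ix = rng.choice(n_genes, size=n_de, replace=False) if n_genes else []
    direction = np.zeros(n_genes)
    direction[de_ix] = np.where(rng.random(n_de) < 0.5, 1, -1)
    de = pd.DataFrame({
        "gene_id": genes["gene_id"],
        "log_fold_change": direction * rng.uniform(0.5, 3.0, n_genes),
        "fdr": np.where(direction != 0, rng.uniform(0, 0.049, n_genes),
                        rng.uniform(0.051, 1.0, n_genes)),
    })

    se_rows = []
    n_hit = int(round(se_hit_frac * n_se))
    se_desert = desert + max(n_peaks, 1) * 1000 + 1_000_000
    for j in range(n_se):
        if j < n_hit and n_peaks:
            pi = int(rng.integers(0, n_peaks))
            s, e = peak_rows[pi][1] - 500, peak_rows[pi][2] + 500
        else:
            s = se_desert + j * 10_000
            e = s + 5000
        se_rows.append((chrom, s, e, j < n_hit and n_peaks > 0))
    super_enhancers = pd.DataFrame(
        se_rows, columns=["chrom", "start", "end", "truth_has_peak"])

    return IntegrationFixture(peaks_a, peaks_b, genes, de, super_enhancers, truth)


def simulate_de_linked_peaks(n_up_genes: int, n_up_peaks: int,
                             n_down_genes: int, n_down_peaks: int,
                             n_other_genes: int = 100,
                             n_other_peaks: int = 200,
                             seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Peak-gene link and DE tables with prescribed direction marginals.

    Builds a cohort-summary fixture in which exactly ``n_up_genes``
    up-regulated genes carry ``n_up_peaks`` peaks in total (every DE gene
    gets >= 1 peak) and likewise for down-regulated genes, plus non-DE
    padding. Used to exercise the direction/bin accounting of
    :func:`rbomics.peaks.integrate_with_de` against known totals.
    """
    if n_up_peaks < n_up_genes or n_down_peaks < n_down_genes:
        raise ValueError("need at least one peak per DE gene")
    rng = np.random.default_rng(seed)
    bins = ("promoter_3kb", "mid_3to10kb", "distal_10to100kb", "far_over100kb")

    link_rows, de_rows = [], []

    def add(prefix, n_genes_grp, n_peaks_grp, lfc_sign, fdr_lo, fdr_hi):
        gene_ids = [f"{prefix}{i:05d}" for i in range(n_genes_grp)]
        for g in gene_ids:
            de_rows.append((g, lfc_sign * float(rng.uniform(0.5, 3.0)),
                            float(rng.uniform(fdr_lo, fdr_hi))))
        owners = list(range(n_genes_grp)) + \
            [int(rng.integers(0, n_genes_grp))
             for _ in range(n_peaks_grp - n_genes_grp)]
        ranges = ((0, 3000), (3001, 10_000), (10_001, 100_000),
                  (100_001, 200_000))
        for gi in owners:
            pos = 1000 * (len(link_rows) + 1)
            bi = int(rng.integers(0, 4))
            lo, hi = ranges[bi]
            d = int(rng.integers(lo, hi + 1))
            link_rows.append(("chr1", pos, pos + 200, gene_ids[gi],
                              float(d if rng.random() < 0.5 else -d), bins[bi]))

    add("UP", n_up_genes, n_up_peaks, +1, 0.0, 0.049)
    add("DN", n_down_genes, n_down_peaks, -1, 0.0, 0.049)
    add("NS", n_other_genes, n_other_peaks, +1, 0.051, 1.0)

    links = pd.DataFrame(link_rows, columns=["chrom", "start", "end",
                                             "gene_id", "signed_distance", "bin"])
    de = pd.DataFrame(de_rows, columns=["gene_id", "log_fold_change", "fdr"])
    return links, de


# ---------------------------------------------------------------------------
# single-cell count matrix


def simulate_count_matrix(n_cells: int, n_genes: int,
                          frac_lowq: float = 0.1,
                          mito_gene_frac: float = 0.05,
                          seed: int = 0,
                          ) -> tuple[sp.csc_matrix, list[str], list[str], pd.DataFrame]:
    """Sparse genes x cells count matrix with planted QC failures.

    Each planted low-quality cell violates exactly one QC rule: total UMI
    <= 400 (fail_umi), genes detected < 100 (fail_genes) or mitochondrial
    fraction >= 10% (fail_mito); all other cells pass every rule with
    margin. Returns (matrix, barcodes, gene_symbols, labels).
    """
    if not 0 <= frac_lowq <= 1 or not 0 <= mito_gene_frac <= 1:
        raise ValueError("fractions must lie in [0, 1]")
    if n_genes < 120:
        raise ValueError("need >= 120 genes to build passing cells")
    rng = np.random.default_rng(seed)
    n_mito = max(2, int(round(mito_gene_frac * n_genes)))
    gene_symbols = [f"MT-M{i}" for i in range(n_mito)] + \
        [f"GENE{i}" for i in range(n_genes - n_mito)]
    nonmito_ix = np.arange(n_mito, n_genes)

    n_low = int(round(frac_lowq * n_cells))
    modes = [("fail_umi", "fail_genes", "fail_mito")[i % 3] for i in range(n_low)]
    labels = modes + ["pass"] * (n_cells - n_low)
    order = rng.permutation(n_cells)
    labels = [labels[i] for i in order]

    rows_ix, cols_ix, vals = [], [], []

    def plant(cell: int, total: int, n_detect_nonmito: int, mito_frac: float) -> None:
        m = int(round(mito_frac * total))
        g_mito = min(2, m) if m else 0
        gm = rng.choice(n_mito, size=g_mito, replace=False)
        gn = rng.choice(nonmito_ix, size=n_detect_nonmito, replace=False)
        nm_total = total - m
        base = np.ones(n_detect_nonmito, dtype=int)
        extra = rng.multinomial(nm_total - n_detect_nonmito,
                                np.full(n_detect_nonmito, 1 / n_detect_nonmito))
        counts = base + extra
        for g, c in zip(gn, counts):
            rows_ix.append(int(g)); cols_ix.append(cell); vals.append(int(c))
        if g_mito:
            mbase = np.ones(g_mito, dtype=int)
            mextra = rng.multinomial(m - g_mito, np.full(g_mito, 1 / g_mito))
            for g, c in zip(gm, mbase + mextra):
                rows_ix.append(int(g)); cols_ix.append(cell); vals.append(int(c))

    max_detect = min(n_genes - n_mito, 5990)
    for cell, label in enumerate(labels):
        if label == "pass":
            total = int(rng.integers(800, 3000))
            g = int(rng.integers(100, min(max_detect, total // 2)))
            plant(cell, total, g, float(rng.uniform(0.02, 0.08)))
        elif label == "fail_umi":
            plant(cell, 350, 120, 0.05)
        elif label == "fail_genes":
            plant(cell, 1000, 50, 0.05)
        else:  # fail_mito
            plant(cell, 1000, 150, 0.25)

    barcodes = [f"CELL{i:05d}-1" for i in range(n_cells)]
    matrix = sp.coo_matrix((vals, (rows_ix, cols_ix)),
                           shape=(n_genes, n_cells)).tocsc()
    label_df = pd.DataFrame({"barcode": barcodes, "qc_label": labels})
    return matrix, barcodes, gene_symbols, label_df
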