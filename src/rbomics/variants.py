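"""Post-caller somatic variant filtering for tumor-only and matched cohorts.

Calls emitted by a somatic caller still contain recurrent artifacts, residual
germline variants and poorly supported sites. This module applies a cascade
of deterministic filters to a cohort of tumor variant calls:

* panel-of-normals (PoN): drop variants seen in >= 2 unrelated normals;
* read support: drop variants with < 3 alternate tumor reads, or with < 8
  alternate tumor reads when the matched blood carries > 1 alternate read;
* allele fraction: drop variants with tumor VAF < 5% (5% exactly passes);
* population frequency: drop variants at >= 1% minor-allele frequency in
  either of two population panels (unknown frequency passes);
* dbSNP membership: drop known SNPs unless the SNP is rare (< 1% or unknown
  population MAF), maps uniquely to the reference assembly, or carries a
  clinically-associated tag;
* shared indel: an identical insertion, deletion or non-frameshift
  multinucleotide variant recurring in >= 2 tumors without matched germline
  and absent from every matched tumor is treated as a missed germline
  variant and removed cohort-wide.

All rules are evaluated for every variant (no short-circuiting) so the
decision table records the complete set of failing rules per variant; a
variant is kept iff no rule fails. The 5% cutoff is applied to the tumor
variant allele fraction alt/(alt+ref); population frequencies have their own
separate 1% rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

VariantKey = tuple[str, int, str, str]

INDEL_LIKE_TYPES = frozenset({"insertion", "deletion", "MNV_nonframeshift"})

VARIANT_COLUMNS = [
    "sample_id", "chrom", "pos", "ref", "alt",
    "variant_type", "functional_class",
    "tumor_alt_reads", "tumor_ref_reads", "blood_alt_reads", "tumor_vaf",
    "pop_maf_1000g", "pop_maf_esp",
    "in_dbsnp", "dbsnp_pop_maf", "dbsnp_single_mapping", "dbsnp_clinical_tag",
    "matched_normal_available",
]

RULE_PON = "panel_of_normals"
RULE_READ_SUPPORT = "read_support"
RULE_VAF = "vaf"
RULE_POPULATION = "population"
RULE_DBSNP = "dbsnp"
RULE_SHARED_INDEL = "shared_indel"

RULE_ORDER = (RULE_PON, RULE_READ_SUPPORT, RULE_VAF,
              RULE_POPULATION, RULE_DBSNP, RULE_SHARED_INDEL)


class PanelOfNormals:
    """Index of variant keys observed in normal (blood) samples.

    Stores, per (chrom, pos, ref, alt) key, the number of normals carrying
    the variant. Only keys with count >= 1 are stored.
    """

    def __init__(self, counts: Mapping[VariantKey, int] | None = None):
        self._counts: dict[VariantKey, int] = {}
        if counts:
            for key, n in counts.items():
                if n < 1:
                    raise ValueError(f"panel count must be >= 1, got {n} for {key}")
                self._counts[key] = int(n)

    def count(self, key: VariantKey) -> int:
        return self._counts.get(key, 0)

    def add(self, key: VariantKey, n: int = 1) -> None:
        if n < 1:
            raise ValueError("n must be >= 1")
        self._counts[key] = self._counts.get(key, 0) + n

    def __len__(self) -> int:
        return len(self._counts)

    def __contains__(self, key: VariantKey) -> bool:
        return key in self._counts

    def items(self):
        return self._counts.items()

    def to_frame(self) -> pd.DataFrame:
        rows = [(c, p, r, a, n) for (c, p, r, a), n in sorted(self._counts.items())]
        return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "n_normals"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PanelOfNormals":
        counts = {
            (str(r.chrom), int(r.pos), str(r.ref), str(r.alt)): int(r.n_normals)
            for r in df.itertuples()
        }
        return cls(counts)


@dataclass
class FilterConfig:
    """Thresholds of the filter cascade (defaults follow the published rules)."""

    pon_min_normals: int = 2        # fail if key seen in >= this many normals
    min_tumor_alt: int = 3          # fail if tumor alt reads < this
    matched_tumor_alt: int = 8      # with blood support, fail below this
    max_blood_alt: int = 1          # blood alt reads > this counts as support
    min_vaf: float = 0.05           # fail if tumor VAF strictly below
    max_pop_maf: float = 0.01       # fail at or above this population MAF
    shared_indel_min_unmatched: int = 2

    def __post_init__(self) -> None:
        if self.min_tumor_alt < 0 or self.matched_tumor_alt < 0:
            raise ValueError("read thresholds must be non-negative")
        if not 0 <= self.min_vaf <= 1:
            raise ValueError("min_vaf must lie in [0, 1]")


def variant_key(v: Mapping) -> VariantKey:
    return (str(v["chrom"]), int(v["pos"]), str(v["ref"]), str(v["alt"]))


def _is_unknown(x) -> bool:
    return x is None or (isinstance(x, float) and np.isnan(x))


# ---------------------------------------------------------------------------
# per-variant rule predicates; each returns True when the variant FAILS


def pon_filter(v: Mapping, pon: PanelOfNormals, config: FilterConfig | None = None) -> bool:
    cfg = config or FilterConfig()
    return pon.count(variant_key(v)) >= cfg.pon_min_normals


def read_support_filter(v: Mapping, config: FilterConfig | None = None) -> bool:
    cfg = config or FilterConfig()
    alt = v["tumor_alt_reads"]
    if alt < 0:
        raise ValueError("negative tumor_alt_reads")
    if alt < cfg.min_tumor_alt:
        return True
    blood = v.get("blood_alt_reads") if hasattr(v, "get") else v["blood_alt_reads"]
    if _is_unknown(blood):
        return False
    if blood < 0:
        raise ValueError("negative blood_alt_reads")
    return alt < cfg.matched_tumor_alt and blood > cfg.max_blood_alt


def vaf_filter(v: Mapping, config: FilterConfig | None = None) -> bool:
    cfg = config or FilterConfig()
    return float(v["tumor_vaf"]) < cfg.min_vaf


def population_filter(v: Mapping, config: FilterConfig | None = None) -> bool:
    cfg = config or FilterConfig()
    for field_name in ("pop_maf_1000g", "pop_maf_esp"):
        maf = v[field_name]
        if not _is_unknown(maf) and maf >= cfg.max_pop_maf:
            return True
    return False


def dbsnp_filter(v: Mapping, config: FilterConfig | None = None) -> bool:
    cfg = config or FilterConfig()
    if not bool(v["in_dbsnp"]):
        return False
    maf = v["dbsnp_pop_maf"]
    rare_or_unknown = _is_unknown(maf) or maf < cfg.max_pop_maf
    single = v["dbsnp_single_mapping"]
    single = (not _is_unknown(single)) and bool(single)
    clinical = bool(v["dbsnp_clinical_tag"])
    return not (rare_or_unknown or single or clinical)


def shared_indel_keys(cohort: pd.DataFrame,
                      config: FilterConfig | None = None) -> set[VariantKey]:
    """Keys failed by the cohort-wide shared-indel germline heuristic."""
    cfg = config or FilterConfig()
    sub = cohort[cohort["variant_type"].isin(INDEL_LIKE_TYPES)]
    if sub.empty:
        return set()
    failed: set[VariantKey] = set()
    grouped = sub.groupby(["chrom", "pos", "ref", "alt"], sort=False)
    for key, grp in grouped:
        matched = grp["matched_normal_available"].astype(bool)
        n_unmatched = grp.loc[~matched, "sample_id"].nunique()
        n_matched = grp.loc[matched, "sample_id"].nunique()
        if n_unmatched >= cfg.shared_indel_min_unmatched and n_matched == 0:
            failed.add((str(key[0]), int(key[1]), str(key[2]), str(key[3])))
    return failed


# ---------------------------------------------------------------------------
# vectorized cascade


def run_cascade(cohort: pd.DataFrame, pon: PanelOfNormals,
                config: FilterConfig | None = None,
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the full filter cascade to a cohort table.

    Parameters
    ----------
    cohort
        One row per called variant per sample, with the columns of
        ``VARIANT_COLUMNS``. Unknown values are NaN/None.
    pon
        Panel of normals built from unrelated blood samples.

    Returns
    -------
    decisions, kept
        ``decisions`` mirrors the input keys plus ``kept`` (bool) and
        ``failed_rules`` (comma-joined rule ids in cascade order, empty when
        kept); ``kept`` is the subset of input rows that pass every rule.
    """
    cfg = config or FilterConfig()
    if cohort.empty:
        decisions = pd.DataFrame(
            columns=["sample_id", "chrom", "pos", "ref", "alt", "kept", "failed_rules"])
        return decisions, cohort.copy()

    if (cohort["tumor_alt_reads"] < 0).any():
        raise ValueError("negative tumor_alt_reads in cohort")
    blood = pd.to_numeric(cohort["blood_alt_reads"], errors="coerce")
    if (blood.dropna() < 0).any():
        raise ValueError("negative blood_alt_reads in cohort")

    keys = list(zip(cohort["chrom"].astype(str), cohort["pos"].astype(int),
                    cohort["ref"].astype(str), cohort["alt"].astype(str)))

    pon_fail = np.array([pon.count(k) >= cfg.pon_min_normals for k in keys])

    alt = cohort["tumor_alt_reads"].to_numpy()
    blood_support = (blood > cfg.max_blood_alt).fillna(False).to_numpy(dtype=bool)
    read_fail = (alt < cfg.min_tumor_alt) | \
        ((alt < cfg.matched_tumor_alt) & blood_support)

    vaf_fail = cohort["tumor_vaf"].to_numpy(dtype=float) < cfg.min_vaf

    g1k = pd.to_numeric(cohort["pop_maf_1000g"], errors="coerce")
    esp = pd.to_numeric(cohort["pop_maf_esp"], errors="coerce")
    pop_fail = ((g1k >= cfg.max_pop_maf).fillna(False)
                | (esp >= cfg.max_pop_maf).fillna(False)).to_numpy(dtype=bool)

    in_dbsnp = cohort["in_dbsnp"].astype(bool).to_numpy()
    dmaf = pd.to_numeric(cohort["dbsnp_pop_maf"], errors="coerce")
    rare_or_unknown = (dmaf < cfg.max_pop_maf) | dmaf.isna()
    single = cohort["dbsnp_single_mapping"]
    single = pd.Series(single).fillna(False).astype(bool).to_numpy()
    clinical = cohort["dbsnp_clinical_tag"].astype(bool).to_numpy()
    exception = rare_or_unknown.to_numpy(dtype=bool) | single | clinical
    dbsnp_fail = in_dbsnp & ~exception

    shared = shared_indel_keys(cohort, cfg)
    shared_fail = np.array([k in shared for k in keys])

    fails = {
        RULE_PON: pon_fail,
        RULE_READ_SUPPORT: read_fail,
        RULE_VAF: vaf_fail,
        RULE_POPULATION: pop_fail,
        RULE_DBSNP: dbsnp_fail,
        RULE_SHARED_INDEL: shared_fail,
    }
    failed_rules = [
        ",".join(rule for rule in RULE_ORDER if fails[rule][i])
        for i in range(len(cohort))
    ]
    kept_mask = ~np.logical_or.reduce(list(fails.values()))

    decisions = cohort[["sample_id", "chrom", "pos", "ref", "alt"]].copy()
    decisions["kept"] = kept_mask
    decisions["failed_rules"] = failed_rules
    kept = cohort.loc[kept_mask].reset_index(drop=True)
    return decisions, kept


def build_pon_from_normals(normal_tables: Iterable[pd.DataFrame]) -> PanelOfNormals:
    """Build a panel from per-normal variant tables (chrom, pos, ref, alt)."""
    pon = PanelOfNormals()
    for table in normal_tables:
        seen = {variant_key(row) for _, row in table.iterrows()}
        for key in seen:
            pon.add(key)
    return pon
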