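"""Single-cell RNA-seq quality control and detection summaries.

Cells are kept when total UMI count exceeds 400 (strict), the number of
detected genes lies in [100, 6000] (inclusive) and the mitochondrial UMI
fraction is below 10% (strict). Mitochondrial genes are identified by symbol
prefix (default "MT-") or an explicit list. Per-group summaries report the
fraction of cells detecting a gene (raw count > 0) and its mean log1p CPM;
gene-gene co-detection is tested with Fisher's exact test on the 2x2
detection table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import fisher_exact

RULE_UMI = "fail_umi"
RULE_GENES = "fail_genes"
RULE_MITO = "fail_mito"


@dataclass
class QCThresholds:
    min_umi: int = 400            # keep iff total UMI strictly greater
    min_genes: int = 100          # inclusive
    max_genes: int = 6000         # inclusive
    max_mito_fraction: float = 0.10  # keep iff strictly below


def _as_csc(counts) -> sp.csc_matrix:
    m = sp.csc_matrix(counts)
    if (m.data < 0).any():
        raise ValueError("counts must be non-negative")
    return m


def mito_mask(gene_symbols: pd.Index | list[str],
              mito_prefix: str = "MT-",
              mito_genes: list[str] | None = None) -> np.ndarray:
    symbols = pd.Index(gene_symbols)
    if mito_genes is not None:
        return np.asarray(symbols.isin(mito_genes))
    return np.array([s.startswith(mito_prefix) for s in symbols])


def qc_filter(counts, barcodes: list[str], gene_symbols: list[str],
              mito_prefix: str = "MT-",
              mito_genes: list[str] | None = None,
              thresholds: QCThresholds | None = None,
              ) -> tuple[pd.DataFrame, sp.csc_matrix, list[str]]:
    """Per-cell QC report and the filtered matrix.

    ``counts`` is genes x cells (sparse or dense). Returns (report,
    filtered_counts, kept_barcodes); the report has one row per input cell
    with total_umi, n_genes_detected, mito_fraction, pass and failed_rules.
    """
    th = thresholds or QCThresholds()
    m = _as_csc(counts)
    if m.shape[0] != len(gene_symbols) or m.shape[1] != len(barcodes):
        raise ValueError("matrix shape does not match barcodes/genes")
    if len(set(barcodes)) != len(barcodes):
        raise ValueError("barcodes must be unique")

    total = np.asarray(m.sum(axis=0)).ravel()
    n_genes = m.astype(bool).sum(axis=0)
    n_genes = np.asarray(n_genes).ravel()
    mito = mito_mask(gene_symbols, mito_prefix, mito_genes)
    mito_umi = np.asarray(m[mito, :].sum(axis=0)).ravel() if mito.any() \
        else np.zeros(m.shape[1])
    with np.errstate(invalid="ignore"):
        mito_frac = np.where(total > 0, mito_umi / np.maximum(total, 1), 0.0)

    failed = []
    for t, g, f in zip(total, n_genes, mito_frac):
        rules = []
        if not t > th.min_umi:
            rules.append(RULE_UMI)
        if not th.min_genes <= g <= th.max_genes:
            rules.append(RULE_GENES)
        if not f < th.max_mito_fraction:
            rules.append(RULE_MITO)
        failed.append(rules)

    report = pd.DataFrame({
        "barcode": barcodes,
        "total_umi": total.astype(int),
        "n_genes_detected": n_genes.astype(int),
        "mito_fraction": mito_frac,
        "pass": [not r for r in failed],
        "failed_rules": [",".join(r) for r in failed],
    })
    keep = report["pass"].to_numpy()
    kept_barcodes = [b for b, k in zip(barcodes, keep) if k]
    return report, m[:, keep], kept_barcodes


def cpm_log1p(counts) -> np.ndarray:
    """Dense log1p counts-per-million normalization (genes x cells)."""
    m = _as_csc(counts).toarray().astype(float)
    total = m.sum(axis=0)
    scale = np.divide(1e6, total, out=np.zeros_like(total), where=total > 0)
    return np.log1p(m * scale[None, :])


def group_expression_summary(counts, barcodes: list[str],
                             gene_symbols: list[str],
                             cell_groups: dict[str, str],
                             genes: list[str]) -> pd.DataFrame:
    """Per-group detection fraction and mean log1p CPM for selected genes.

    ``cell_groups`` maps barcode -> group label; cells without a label are
    ignored. Detection uses raw counts (> 0); expression uses log1p CPM.
    """
    m = _as_csc(counts)
    sym_ix = {g: i for i, g in enumerate(gene_symbols)}
    missing = [g for g in genes if g not in sym_ix]
    if missing:
        raise KeyError(f"genes absent from matrix: {missing}")
    norm = cpm_log1p(m)
    rows = []
    groups = sorted(set(cell_groups.values()))
    bc_ix = {b: i for i, b in enumerate(barcodes)}
    for group in groups:
        cols = np.array([bc_ix[b] for b, g in cell_groups.items()
                         if g == group and b in bc_ix], dtype=int)
        for gene in genes:
            gi = sym_ix[gene]
            if len(cols) == 0:
                rows.append((group, gene, 0.0, 0.0, 0))
                continue
            raw = np.asarray(m[gi, cols].todense()).ravel()
            rows.append((group, gene, float((raw > 0).mean()),
                         float(norm[gi, cols].mean()), len(cols)))
    return pd.DataFrame(rows, columns=["group", "gene", "fraction_detected",
                                       "mean_log1p_cpm", "n_cells"])


def codetection_association(counts, gene_symbols: list[str],
                            gene_a: str, gene_b: str) -> dict:
    """2x2 detection table, odds ratio and two-sided Fisher exact p.

    Cells are cross-classified by detection (count > 0) of each gene. A
    degenerate table with an empty margin gives odds_ratio = inf when the
    diagonal dominates (e.g. gene_b identical to gene_a).
    """
    m = _as_csc(counts)
    sym_ix = {g: i for i, g in enumerate(gene_symbols)}
    a = np.asarray(m[sym_ix[gene_a], :].todense()).ravel() > 0
    b = np.asarray(m[sym_ix[gene_b], :].todense()).ravel() > 0
    table = np.array([[int((a & b).sum()), int((a & ~b).sum())],
                      [int((~a & b).sum()), int((~a & ~b).sum())]])
    odds, p = fisher_exact(table, alternative="two-sided")
    return {"table": table, "odds_ratio": float(odds), "p": float(p)}
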