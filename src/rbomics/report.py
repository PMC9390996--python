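"""Cohort-level reporting: printed percentages and oncoprint matrix export.

``percentage`` implements the manuscript-style rounding convention
(round-half-up to one decimal, computed exactly on integers so no binary
floating-point artifact can flip a boundary case). ``build_oncoprint``
collapses per-sample alterations into a gene x sample matrix using a
configurable alteration-priority order and reports per-gene counts and
frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

DEFAULT_PRIORITY = ("homozygous_deletion", "stop_gain", "splicing",
                    "indel", "missense", "none")


def percentage(count: int, total: int) -> float:
    """100 * count / total, rounded half-up to one decimal place."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= count <= total:
        raise ValueError("count must lie in [0, total]")
    # exact integer arithmetic: value = 1000*count/total tenths-of-a-percent
    q, r = divmod(1000 * count, total)
    if 2 * r >= total:
        q += 1
    return q / 10.0


@dataclass
class CohortSummary:
    n_samples: int
    matrix: pd.DataFrame                       # gene x sample alteration codes
    gene_counts: pd.Series = field(default=None)   # samples altered per gene
    gene_frequencies: pd.Series = field(default=None)

    def frequency_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "gene": self.gene_counts.index,
            "n_altered": self.gene_counts.values,
            "percent": [percentage(int(c), self.n_samples)
                        for c in self.gene_counts.values],
        })


def build_oncoprint(alterations: pd.DataFrame,
                    samples: list[str] | None = None,
                    priority: tuple[str, ...] = DEFAULT_PRIORITY,
                    ) -> CohortSummary:
    """Build a gene x sample oncoprint matrix from an alteration table.

    ``alterations`` has one row per alteration: sample_id, gene,
    alteration_type (values drawn from ``priority``; earlier wins when a
    sample carries several alterations of one gene). ``samples`` fixes the
    cohort and its size; defaults to the samples present in the table.
    Columns are ordered by total alteration burden, descending.
    """
    if samples is None:
        samples = sorted(alterations["sample_id"].unique())
    unknown = set(alterations["alteration_type"]) - set(priority)
    if unknown:
        raise ValueError(f"alteration types outside priority order: {unknown}")
    prio = {a: i for i, a in enumerate(priority)}
    genes = sorted(alterations["gene"].unique())

    matrix = pd.DataFrame("none", index=genes, columns=samples)
    for r in alterations.itertuples():
        if r.sample_id not in matrix.columns:
            continue
        current = matrix.at[r.gene, r.sample_id]
        if prio[r.alteration_type] < prio[current]:
            matrix.at[r.gene, r.sample_id] = r.alteration_type

    altered = matrix != "none"
    burden = altered.sum(axis=0).sort_values(ascending=False, kind="stable")
    matrix = matrix[burden.index]
    gene_counts = altered.sum(axis=1).sort_values(ascending=False, kind="stable")
    n = len(samples)
    freqs = gene_counts.map(lambda c: percentage(int(c), n)) if n else gene_counts
    return CohortSummary(n_samples=n, matrix=matrix,
                         gene_counts=gene_counts, gene_frequencies=freqs)
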