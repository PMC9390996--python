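"""Readers and writers for the plain-text formats the pipeline exchanges.

Conventions: BED intervals are 0-based half-open; TSS and VCF positions are
1-based. Unknown numeric fields round-trip as empty TSV cells / NaN.
"""

from __future__ import annotations

import os

import pandas as pd
import scipy.io
import scipy.sparse as sp

from .variants import PanelOfNormals

_BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = _BED_COLUMNS[: df.shape[1]]
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in _BED_COLUMNS if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_gene_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str,
                                              "strand": str})


def write_gene_tsv(df: pd.DataFrame, path) -> None:
    df[["gene_id", "chrom", "tss", "strand"]].to_csv(path, sep="\t", index=False)


def read_de_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_de_tsv(df: pd.DataFrame, path) -> None:
    df[["gene_id", "log_fold_change", "fdr"]].to_csv(path, sep="\t", index=False)


def read_variant_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_variant_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_segments_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_segments_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_pon_tsv(path) -> PanelOfNormals:
    return PanelOfNormals.from_frame(pd.read_csv(path, sep="\t"))


def write_pon_tsv(pon: PanelOfNormals, path) -> None:
    pon.to_frame().to_csv(path, sep="\t", index=False)


def write_vcf_minimal(variants: pd.DataFrame, path) -> None:
    """Write a minimal VCF 4.2 with per-sample AD (ref,alt depths)."""
    samples = sorted(variants["sample_id"].unique())
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                 'Description="Allelic depths">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        key_cols = ["chrom", "pos", "ref", "alt"]
        for key, grp in variants.sort_values(key_cols).groupby(key_cols, sort=True):
            chrom, pos, ref, alt = key
            per_sample = {
                r.sample_id: f"{int(r.tumor_ref_reads)},{int(r.tumor_alt_reads)}"
                for r in grp.itertuples()}
            cells = [per_sample.get(s, ".") for s in samples]
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t.\tAD\t"
                     + "\t".join(cells) + "\n")


def write_mtx(out_dir, matrix: sp.spmatrix, barcodes: list[str],
              gene_symbols: list[str]) -> None:
    """CellRanger-style layout: matrix.mtx, barcodes.tsv, features.tsv."""
    os.makedirs(out_dir, exist_ok=True)
    scipy.io.mmwrite(os.path.join(out_dir, "matrix.mtx"), sp.coo_matrix(matrix))
    with open(os.path.join(out_dir, "barcodes.tsv"), "w") as fh:
        fh.write("\n".join(barcodes) + ("\n" if barcodes else ""))
    with open(os.path.join(out_dir, "features.tsv"), "w") as fh:
        for g in gene_symbols:
            fh.write(f"{g}\t{g}\tGene Expression\n")


def read_mtx(in_dir) -> tuple[sp.csc_matrix, list[str], list[str]]:
    matrix = sp.csc_matrix(scipy.io.mmread(os.path.join(in_dir, "matrix.mtx")))
    with open(os.path.join(in_dir, "barcodes.tsv")) as fh:
        barcodes = [line.strip() for line in fh if line.strip()]
    with open(os.path.join(in_dir, "features.tsv")) as fh:
        genes = [line.split("\t")[0].strip() for line in fh if line.strip()]
    return matrix, barcodes, genes
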