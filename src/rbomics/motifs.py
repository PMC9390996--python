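"""Known-motif scanning, presence/co-occurrence matrices and enrichment.

Motifs are either IUPAC consensus strings (e.g. the ERRE half-site class
TNAAGGTCA) or position weight matrices scored by log-odds against a
background; a PWM hit requires at least ``score_threshold`` x the maximum
attainable score. Scanning is double-stranded and 'N' in the sequence never
matches. Per-region presence feeds UpSet-style exact co-occurrence counts
and a one-sided hypergeometric enrichment test of target regions against a
background, BH-adjusted across motifs.

The bundled default motif models (ERRE, CRX/OTX2, NEUROD, LHX) are compact
consensus approximations of public motif-collection entries, provided so the
pipeline runs end-to-end; real analyses should load curated matrices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control, hypergeom

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class MotifModel:
    """A named binding-site model: IUPAC consensus or 4xL weight matrix."""

    name: str
    consensus: str | None = None
    pwm: np.ndarray | None = None          # shape (4, L), columns sum to 1
    background: np.ndarray | None = None   # length 4, default uniform
    score_threshold: float = 0.8           # fraction of max log-odds score

    def __post_init__(self) -> None:
        if (self.consensus is None) == (self.pwm is None):
            raise ValueError("provide exactly one of consensus or pwm")
        if self.consensus is not None:
            bad = set(self.consensus.upper()) - set(IUPAC)
            if bad:
                raise ValueError(f"non-IUPAC codes in consensus: {bad}")
            self.consensus = self.consensus.upper()
        else:
            self.pwm = np.asarray(self.pwm, dtype=float)
            if self.pwm.shape[0] != 4:
                raise ValueError("pwm must have 4 rows (A, C, G, T)")
            if not np.allclose(self.pwm.sum(axis=0), 1.0):
                raise ValueError("pwm columns must sum to 1")
            if self.background is None:
                self.background = np.full(4, 0.25)
            if not 0 <= self.score_threshold <= 1:
                raise ValueError("score_threshold must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.consensus) if self.consensus is not None else self.pwm.shape[1]


def default_motifs() -> list[MotifModel]:
    """Compact consensus models for the retina-associated motif panel."""
    return [
        MotifModel("ERRE", consensus="TNAAGGTCA"),
        MotifModel("CRX_OTX2", consensus="TAATCC"),
        MotifModel("NEUROD", consensus="CAGCTG"),
        MotifModel("LHX", consensus="TAATTA"),
    ]


def _consensus_hits_one_strand(seq: str, pattern: str) -> list[int]:
    L = len(pattern)
    allowed = [IUPAC[c] for c in pattern]
    hits = []
    for i in range(len(seq) - L + 1):
        window = seq[i:i + L]
        if all(base in allow for base, allow in zip(window, allowed)):
            hits.append(i)
    return hits


def _pwm_logodds(motif: MotifModel, pseudo: float = 1e-6) -> np.ndarray:
    return np.log2((motif.pwm + pseudo) / (motif.background[:, None] + pseudo))


def scan(sequence: str, motif: MotifModel) -> pd.DataFrame:
    """Find motif hits on both strands of a sequence.

    Returns a frame with columns position (0-based offset on the forward
    strand), strand and score (1.0 for consensus hits, log-odds for PWM
    hits). A motif longer than the sequence yields an empty frame; windows
    containing N never match.
    """
    seq = sequence.upper()
    rows: list[tuple[int, str, float]] = []
    if len(motif) > len(seq):
        return pd.DataFrame(columns=["position", "strand", "score"])
    if motif.consensus is not None:
        fwd = motif.consensus
        rev = reverse_complement(fwd)
        for i in _consensus_hits_one_strand(seq, fwd):
            rows.append((i, "+", 1.0))
        for i in _consensus_hits_one_strand(seq, rev):
            rows.append((i, "-", 1.0))
        # an N in the sequence is not a concrete base: exclude windows with N
        rows = [r for r in rows if "N" not in seq[r[0]:r[0] + len(motif)]]
    else:
        lo = _pwm_logodds(motif)
        max_score = lo.max(axis=0).sum()
        cutoff = motif.score_threshold * max_score
        L = len(motif)
        lo_rc = lo[::-1, ::-1]  # reverse-complement scoring matrix
        for i in range(len(seq) - L + 1):
            window = seq[i:i + L]
            if "N" in window:
                continue
            idx = [_BASE_INDEX[b] for b in window]
            fwd_score = float(sum(lo[b, j] for j, b in enumerate(idx)))
            rev_score = float(sum(lo_rc[b, j] for j, b in enumerate(idx)))
            if fwd_score >= cutoff:
                rows.append((i, "+", fwd_score))
            if rev_score >= cutoff:
                rows.append((i, "-", rev_score))
    out = pd.DataFrame(rows, columns=["position", "strand", "score"])
    return out.sort_values(["position", "strand"]).reset_index(drop=True)


def presence_matrix(sequences: Mapping[str, str],
                    motifs: Sequence[MotifModel]) -> pd.DataFrame:
    """Boolean region x motif presence matrix (>= 1 hit per cell)."""
    names = [m.name for m in motifs]
    if len(set(names)) != len(names):
        raise ValueError("motif names must be unique")
    data = {
        m.name: [len(scan(seq, m)) > 0 for seq in sequences.values()]
        for m in motifs
    }
    return pd.DataFrame(data, index=list(sequences.keys()))


def tss_windows(genome: Mapping[str, str], genes: pd.DataFrame,
                flank: int = 3000) -> dict[str, str]:
    """Extract TSS +/- flank windows (on the forward strand) per gene."""
    windows = {}
    for g in genes.itertuples():
        seq = genome[g.chrom]
        tss0 = int(g.tss) - 1
        lo, hi = max(tss0 - flank, 0), min(tss0 + flank + 1, len(seq))
        windows[str(g.gene_id)] = seq[lo:hi]
    return windows


def cooccurrence_counts(matrix: pd.DataFrame) -> pd.DataFrame:
    """Count rows by their exact set of present motifs (UpSet semantics).

    Every row contributes to exactly one subset; subset counts therefore sum
    to the number of rows. Returns columns subset ('&'-joined motif names,
    '' for the empty set) and count, sorted by descending count.
    """
    cols = list(matrix.columns)
    keys = matrix.apply(lambda row: "&".join(c for c in cols if row[c]), axis=1)
    counts = keys.value_counts()
    out = counts.rename_axis("subset").reset_index(name="count")
    return out.sort_values(["count", "subset"], ascending=[False, True]
                           ).reset_index(drop=True)


def enrichment_test(matrix: pd.DataFrame,
                    target_rows: Iterable[str],
                    background_rows: Iterable[str] | None = None,
                    randomize_ties: bool = False,
                    seed: int | None = None) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of motif presence.

    Tests, per motif, whether presence is over-represented among
    ``target_rows`` relative to the universe target + background (background
    defaults to all non-target rows of the matrix). ``randomize_ties`` draws
    the randomized p-value P(X > x) + U * P(X = x), which is exactly uniform
    under the null and is the appropriate mode for calibration studies;
    the default reports the standard conservative tail P(X >= x).
    Returns motif, n_target, k_target, n_background, k_background, p, fdr.
    """
    target = list(target_rows)
    if background_rows is None:
        background = [r for r in matrix.index if r not in set(target)]
    else:
        background = list(background_rows)
    universe = target + background
    missing = set(universe) - set(matrix.index)
    if missing:
        raise KeyError(f"rows absent from matrix: {sorted(missing)[:5]}")
    rng = np.random.default_rng(seed)

    sub = matrix.loc[universe]
    t = matrix.loc[target]
    rows = []
    M, N = len(universe), len(target)
    for motif in matrix.columns:
        K = int(sub[motif].sum())
        k = int(t[motif].sum())
        if randomize_ties:
            p = float(hypergeom.sf(k, M, K, N)
                      + rng.random() * hypergeom.pmf(k, M, K, N))
        else:
            p = float(hypergeom.sf(k - 1, M, K, N))
        rows.append((motif, N, k, M - N, K - k, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["motif", "n_target", "k_target",
                                      "n_background", "k_background", "p"])
    out["fdr"] = false_discovery_control(out["p"], method="bh")
    return out
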