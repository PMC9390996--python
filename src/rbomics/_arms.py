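"""Chromosome-arm interval table for hg19.

Arm boundaries are derived from the UCSC hg19 cytoband/gap tracks: the p arm
runs from the chromosome start to the centromere start, the q arm from the
centromere end to the chromosome end. The five acrocentric p arms (13p, 14p,
15p, 21p, 22p) are excluded, leaving the 39 autosomal arms conventionally
scored in arm-level copy-number analyses. Coordinates are 0-based half-open.
"""

from __future__ import annotations

import pandas as pd

# chrom -> (length, centromere_start, centromere_end)
_HG19_CHROMS: dict[str, tuple[int, int, int]] = {
    "chr1": (249250621, 121535434, 124535434),
    "chr2": (243199373, 92326171, 95326171),
    "chr3": (198022430, 90504854, 93504854),
    "chr4": (191154276, 49660117, 52660117),
    "chr5": (180915260, 46405641, 49405641),
    "chr6": (171115067, 58830166, 61830166),
    "chr7": (159138663, 58054331, 61054331),
    "chr8": (146364022, 43838887, 46838887),
    "chr9": (141213431, 47367679, 50367679),
    "chr10": (135534747, 39254935, 42254935),
    "chr11": (135006516, 51644205, 54644205),
    "chr12": (133851895, 34856694, 37856694),
    "chr13": (115169878, 16000000, 19000000),
    "chr14": (107349540, 16000000, 19000000),
    "chr15": (102531392, 17000000, 20000000),
    "chr16": (90354753, 35335801, 38335801),
    "chr17": (81195210, 22263006, 25263006),
    "chr18": (78077248, 15460898, 18460898),
    "chr19": (59128983, 24681782, 27681782),
    "chr20": (63025520, 26369569, 29369569),
    "chr21": (48129895, 11288129, 14288129),
    "chr22": (51304566, 13000000, 16000000),
}

_ACROCENTRIC_P = {"13p", "14p", "15p", "21p", "22p"}


def hg19_arm_table() -> pd.DataFrame:
    """Return the default arm table: columns arm, chrom, start, end."""
    rows = []
    for chrom, (length, cen_start, cen_end) in _HG19_CHROMS.items():
        num = chrom.removeprefix("chr")
        p_name, q_name = f"{num}p", f"{num}q"
        if p_name not in _ACROCENTRIC_P:
            rows.append((p_name, chrom, 0, cen_start))
        rows.append((q_name, chrom, cen_end, length))
    return pd.DataFrame(rows, columns=["arm", "chrom", "start", "end"])


def chrom_length(chrom: str) -> int:
    return _HG19_CHROMS[chrom][0]


ARM_TABLE = hg19_arm_table()
ARM_NAMES = tuple(ARM_TABLE["arm"])
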