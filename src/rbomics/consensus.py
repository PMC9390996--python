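"""Two-of-three predictor consensus for variant deleteriousness.

Each kept SNV carries categorical calls from three effect predictors:
PolyPhen-2 (probably_damaging / possibly_damaging / benign), FATHMM
(damaging / tolerated) and MetaLR (damaging / tolerated). Probably damaging,
possibly damaging and damaging all count as a deleterious vote; benign and
tolerated count as a benign vote.

The consensus rule depends on the variant's functional class:

* nonexonic or synonymous SNVs are deleterious iff >= 2 predictors vote
  deleterious (default: not deleterious when votes are missing);
* nonsynonymous exonic SNVs are NOT deleterious iff >= 2 predictors vote
  benign (default: deleterious when votes are missing);
* exonic insertions/deletions and splicing variants are always deleterious.

The two SNV rules are complementary 2-of-3 formulations and coincide
whenever all three calls are present; they differ only in which way missing
calls break. That asymmetry is applied literally, as worded above.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

POLYPHEN_LEVELS = ("probably_damaging", "possibly_damaging", "benign", "missing")
BINARY_LEVELS = ("damaging", "tolerated", "missing")

_DELETERIOUS_CALLS = {"probably_damaging", "possibly_damaging", "damaging"}
_BENIGN_CALLS = {"benign", "tolerated"}

RULE_NONEXONIC_SYNONYMOUS = "nonexonic_synonymous"
RULE_NONSYN_EXONIC = "nonsynonymous_exonic"
RULE_INDEL_SPLICING = "indel_or_splicing"


@dataclass(frozen=True)
class PredictorCalls:
    polyphen: str = "missing"
    fathmm: str = "missing"
    metalr: str = "missing"

    def __post_init__(self) -> None:
        if self.polyphen not in POLYPHEN_LEVELS:
            raise ValueError(f"invalid PolyPhen-2 call: {self.polyphen!r}")
        for name in ("fathmm", "metalr"):
            if getattr(self, name) not in BINARY_LEVELS:
                raise ValueError(f"invalid {name} call: {getattr(self, name)!r}")


@dataclass(frozen=True)
class DeleteriousnessCall:
    deleterious: bool
    rule_used: str


def binarize(call: str) -> str:
    """Map a raw predictor category to deleterious / benign / missing vote."""
    if call in _DELETERIOUS_CALLS:
        return "deleterious"
    if call in _BENIGN_CALLS:
        return "benign"
    if call == "missing":
        return "missing"
    raise ValueError(f"unknown predictor call: {call!r}")


def _votes(p: PredictorCalls) -> tuple[int, int]:
    votes = [binarize(c) for c in (p.polyphen, p.fathmm, p.metalr)]
    return votes.count("deleterious"), votes.count("benign")


def classify(v: Mapping, p: PredictorCalls) -> DeleteriousnessCall:
    """Classify one kept variant as deleterious or not.

    ``v`` needs ``variant_type`` and ``functional_class``. Indels and MNVs in
    exonic regions and splicing-junction variants are deleterious regardless
    of predictor calls; SNVs go through the class-dependent 2-of-3 vote.
    """
    vtype = v["variant_type"]
    fclass = v["functional_class"]
    if vtype != "SNV" or fclass == "splicing":
        return DeleteriousnessCall(True, RULE_INDEL_SPLICING)
    n_del, n_ben = _votes(p)
    if fclass in ("nonexonic", "synonymous"):
        return DeleteriousnessCall(n_del >= 2, RULE_NONEXONIC_SYNONYMOUS)
    if fclass == "nonsynonymous_exonic":
        return DeleteriousnessCall(not (n_ben >= 2), RULE_NONSYN_EXONIC)
    raise ValueError(f"SNV with unknown functional_class: {fclass!r}")


def classify_table(kept: pd.DataFrame) -> pd.DataFrame:
    """Append ``deleterious`` and ``consensus_rule`` columns to a kept-variant table.

    Expects predictor columns ``polyphen``, ``fathmm``, ``metalr``; missing
    values (NaN or "missing") count as absent calls.
    """
    def norm(x) -> str:
        if x is None or (isinstance(x, float) and pd.isna(x)):
            return "missing"
        return str(x)

    deleterious, rules = [], []
    for row in kept.itertuples(index=False):
        calls = PredictorCalls(norm(row.polyphen), norm(row.fathmm), norm(row.metalr))
        result = classify({"variant_type": row.variant_type,
                           "functional_class": row.functional_class}, calls)
        deleterious.append(result.deleterious)
        rules.append(result.rule_used)
    out = kept.copy()
    out["deleterious"] = deleterious
    out["consensus_rule"] = rules
    return out
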