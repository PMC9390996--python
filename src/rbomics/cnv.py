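"""Arm-level copy-number calling and cohort recurrence testing.

Per-sample copy state is summarized from segmented log2 copy ratios: the
score of a chromosome arm is the length-weighted mean log2 ratio of the
segments overlapping the arm, and an arm is called gained when the score
exceeds +0.1, lost below -0.1, neutral otherwise (strict inequalities, so a
score of exactly 0.1 is neutral).

Cohort-level recurrence is assessed with a permutation analog of the usual
arm-level significance scan: within each sample the vector of arm calls is
permuted across arm labels, preserving each sample's event burden while
breaking arm identity. For every arm x direction the observed event
frequency is converted to a z score against the permutation distribution and
to a permutation p-value; Benjamini-Hochberg adjustment runs across all
arm x direction tests, and an event is significant at z >= 6 and FDR < 0.05.
A focal amplification at a locus (e.g. MYCN at 2p24) is flagged per sample
by the same permutation idea restricted to the locus: the locus score is
compared with scores obtained by permuting the sample's segment ratios, with
an inclusive cutoff of z >= 3.

Copy-neutral loss of heterozygosity (isodisomy) is flagged on arms whose
B-allele frequencies have collapsed to homozygous values (arm-median
|BAF - 0.5| above a deviation threshold, default 0.3) while the arm score
remains within the neutral band |score| <= 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control

from ._arms import ARM_TABLE

GAIN, LOSS, NEUTRAL = "gain", "loss", "neutral"

SEGMENT_COLUMNS = ["sample_id", "chrom", "start", "end", "log2_ratio"]


def _arm_interval(arm: str, arms: pd.DataFrame) -> tuple[str, int, int]:
    row = arms.loc[arms["arm"] == arm]
    if row.empty:
        raise KeyError(f"unknown arm: {arm!r}")
    r = row.iloc[0]
    return str(r["chrom"]), int(r["start"]), int(r["end"])


def _overlap_weights(segments: pd.DataFrame, chrom: str, start: int, end: int
                     ) -> tuple[np.ndarray, np.ndarray]:
    sub = segments[segments["chrom"] == chrom]
    s = np.maximum(sub["start"].to_numpy(), start)
    e = np.minimum(sub["end"].to_numpy(), end)
    w = np.maximum(e - s, 0).astype(float)
    mask = w > 0
    return sub["log2_ratio"].to_numpy(dtype=float)[mask], w[mask]


def arm_score(segments: pd.DataFrame, arm: str,
              arms: pd.DataFrame = ARM_TABLE) -> float:
    """Length-weighted mean log2 ratio of one sample's segments over an arm."""
    chrom, start, end = _arm_interval(arm, arms)
    ratios, weights = _overlap_weights(segments, chrom, start, end)
    if len(ratios) == 0:
        raise ValueError(f"no segments overlap arm {arm}")
    return float(np.average(ratios, weights=weights))


def call_arm(score: float, threshold: float = 0.1) -> str:
    if score > threshold:
        return GAIN
    if score < -threshold:
        return LOSS
    return NEUTRAL


def arm_call_table(cohort_segments: pd.DataFrame,
                   arms: pd.DataFrame = ARM_TABLE,
                   threshold: float = 0.1) -> pd.DataFrame:
    """Score and call every covered arm for every sample.

    Arms with no overlapping segments in a sample are omitted for that
    sample. Returns columns sample_id, arm, arm_score, call.
    """
    rows = []
    for sample_id, seg in cohort_segments.groupby("sample_id", sort=True):
        for arm in arms["arm"]:
            try:
                score = arm_score(seg, arm, arms)
            except ValueError:
                continue
            rows.append((sample_id, arm, score, call_arm(score, threshold)))
    return pd.DataFrame(rows, columns=["sample_id", "arm", "arm_score", "call"])


@dataclass
class RecurrenceResult:
    table: pd.DataFrame  # arm, direction, frequency, z, p, fdr, significant


def recurrence_test(arm_calls: pd.DataFrame,
                    n_perm: int = 10_000,
                    seed: int | None = None,
                    z_cut: float = 6.0,
                    fdr_cut: float = 0.05,
                    randomize_ties: bool = True) -> RecurrenceResult:
    """Permutation test for recurrent arm gains/losses across a cohort.

    ``arm_calls`` is the output of :func:`arm_call_table`. Within each sample
    the calls are permuted across arm labels; the observed per-arm event
    frequency is compared with the permutation distribution.

    ``randomize_ties`` uses the randomized permutation p-value
    p = (#{perm > obs} + U * (#{perm == obs} + 1)) / (n_perm + 1), which is
    exactly uniform under the exchangeable null despite the discreteness of
    frequencies; with ``False`` the conservative tie-inclusive p-value is
    reported instead. Significance calls use the z cutoff plus BH-adjusted
    p-values across all arm x direction tests.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    samples = sorted(arm_calls["sample_id"].unique())
    if len(samples) < 2:
        raise ValueError("recurrence test needs >= 2 samples")
    arms = sorted(arm_calls["arm"].unique())
    rng = np.random.default_rng(seed)

    code = {NEUTRAL: 0, GAIN: 1, LOSS: -1}
    mat = np.zeros((len(samples), len(arms)), dtype=np.int8)
    sample_ix = {s: i for i, s in enumerate(samples)}
    arm_ix = {a: j for j, a in enumerate(arms)}
    for r in arm_calls.itertuples():
        mat[sample_ix[r.sample_id], arm_ix[r.arm]] = code[r.call]

    n_samples, n_arms = mat.shape
    obs = {GAIN: (mat == 1).mean(axis=0), LOSS: (mat == -1).mean(axis=0)}

    # permutation frequencies, chunked to bound memory
    sums = {GAIN: np.zeros(n_arms), LOSS: np.zeros(n_arms)}
    sq = {GAIN: np.zeros(n_arms), LOSS: np.zeros(n_arms)}
    gt = {GAIN: np.zeros(n_arms), LOSS: np.zeros(n_arms)}
    eq = {GAIN: np.zeros(n_arms), LOSS: np.zeros(n_arms)}
    chunk = max(1, min(n_perm, 2_000_000 // (n_samples * n_arms) + 1))
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        order = np.argsort(rng.random((b, n_samples, n_arms)), axis=2)
        perm = np.take_along_axis(np.broadcast_to(mat, (b, n_samples, n_arms)),
                                  order, axis=2)
        for direction, val in ((GAIN, 1), (LOSS, -1)):
            freq = (perm == val).mean(axis=1)  # (b, n_arms)
            sums[direction] += freq.sum(axis=0)
            sq[direction] += (freq ** 2).sum(axis=0)
            gt[direction] += (freq > obs[direction][None, :]).sum(axis=0)
            eq[direction] += (freq == obs[direction][None, :]).sum(axis=0)
        done += b

    rows = []
    for direction in (GAIN, LOSS):
        mean = sums[direction] / n_perm
        var = np.maximum(sq[direction] / n_perm - mean ** 2, 0.0)
        sd = np.sqrt(var)
        for j, arm in enumerate(arms):
            o = obs[direction][j]
            z = 0.0 if sd[j] == 0 else (o - mean[j]) / sd[j]
            if randomize_ties:
                u = rng.random()
                p = (gt[direction][j] + u * (eq[direction][j] + 1)) / (n_perm + 1)
            else:
                p = (gt[direction][j] + eq[direction][j] + 1) / (n_perm + 1)
            rows.append((arm, direction, o, z, p))
    table = pd.DataFrame(rows, columns=["arm", "direction", "frequency", "z", "p"])
    table["fdr"] = false_discovery_control(table["p"], method="bh")
    table["significant"] = (table["z"] >= z_cut) & (table["fdr"] < fdr_cut)
    return RecurrenceResult(table)


def focal_amplification_flag(segments: pd.DataFrame,
                             locus: tuple[str, int, int],
                             z_cut: float = 3.0,
                             n_perm: int = 1000,
                             seed: int | None = None) -> bool:
    """Flag a focal amplification at a locus within one sample.

    The locus score (length-weighted mean log2 ratio over the locus window)
    is compared with scores obtained by permuting the sample's segment
    ratios over its segment layout; flagged iff z >= z_cut (inclusive).
    """
    chrom, start, end = locus
    ratios, weights = _overlap_weights(segments, chrom, start, end)
    if len(ratios) == 0:
        raise ValueError("no segments overlap the locus")
    obs = float(np.average(ratios, weights=weights))

    all_ratios = segments["log2_ratio"].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    k = len(ratios)
    draws = all_ratios[rng.integers(0, len(all_ratios), size=(n_perm, k))]
    perm_scores = draws @ (weights / weights.sum())
    sd = perm_scores.std()
    if sd == 0:
        return bool(obs > perm_scores.mean())
    z = (obs - perm_scores.mean()) / sd
    return bool(z >= z_cut)


def isodisomy_flag(segments: pd.DataFrame, arm: str,
                   baf_dev: float = 0.3,
                   neutral_threshold: float = 0.1,
                   arms: pd.DataFrame = ARM_TABLE) -> bool:
    """Flag copy-neutral LOH on an arm from segment B-allele frequencies.

    True iff the length-weighted median |BAF - 0.5| over the arm exceeds
    ``baf_dev`` while the arm score stays within the neutral band.
    """
    if "baf" not in segments.columns:
        raise ValueError("segments lack a 'baf' column")
    chrom, start, end = _arm_interval(arm, arms)
    sub = segments[(segments["chrom"] == chrom) & segments["baf"].notna()]
    s = np.maximum(sub["start"].to_numpy(), start)
    e = np.minimum(sub["end"].to_numpy(), end)
    w = np.maximum(e - s, 0).astype(float)
    mask = w > 0
    if not mask.any():
        return False
    dev = np.abs(sub["baf"].to_numpy(dtype=float)[mask] - 0.5)
    w = w[mask]
    order = np.argsort(dev)
    cum = np.cumsum(w[order])
    median_dev = dev[order][np.searchsorted(cum, cum[-1] / 2)]
    score = arm_score(segments, arm, arms)
    return bool(median_dev > baf_dev and abs(score) <= neutral_threshold)
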