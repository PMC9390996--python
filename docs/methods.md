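# Methods

This note documents the statistical procedures, default parameters and
design choices behind each module, what the synthetic generators do and do
not emulate, and the package's known limitations.

## Somatic variant filtering

The cascade treats variant identity as the exact `(chrom, pos, ref, alt)`
tuple everywhere. Six independent predicates are evaluated for every
variant — panel of normals, read support, allele fraction, population
frequency, dbSNP, shared indel — and a variant is kept iff none fails.
Because the predicates do not depend on one another's outcomes (the
shared-indel rule is a function of the raw cohort, not of earlier filter
results), evaluation order cannot change the kept set; we still evaluate
all rules rather than short-circuiting so that the decision table records
the complete list of failing rules per variant, which makes filter audits
and ablation studies trivial.

Interpretation choices that the rule wording leaves open:

* The 5% minor-allele-fraction cutoff is applied to the **tumor variant
  allele fraction** alt/(alt+ref), not to a population frequency — the
  population panels have their own, separately stated 1% rule, so reading
  the 5% rule as a second population filter would make it redundant.
  Boundary: strictly below 5% fails; exactly 5% passes.
* The three dbSNP exceptions (rare-or-unknown population MAF, single
  mapping to the reference assembly, clinically-associated tag) are
  OR-combined: any one rescues the variant. This is the reading that keeps
  rare clinically tagged variants. An *unknown* mapping status is not an
  exception.
* With no matched blood, only the absolute alt-read floor (< 3) applies;
  the < 8-with-blood-support clause needs blood evidence by construction.
* Tumor-only samples rely on the panel of normals plus these read-level
  rules; there is no contamination model.

Thresholds live in `FilterConfig` and are monotone in the expected
direction (raising the alt-read or VAF threshold can only shrink the kept
set; property-tested).

## Deleteriousness consensus

Votes: probably damaging / possibly damaging / damaging → deleterious;
benign / tolerated → benign. Exonic indels, multinucleotide variants and
splicing-junction variants are deleterious unconditionally. For SNVs the
rule depends on functional class:

* nonexonic or synonymous: deleterious iff ≥ 2 deleterious votes;
* nonsynonymous exonic: *not* deleterious iff ≥ 2 benign votes.

With three complete calls these are the same Boolean function (verified by
exhaustive enumeration of all 3×2×2 call combinations). They differ only
under missing calls, where each rule is applied literally as worded,
producing asymmetric defaults: a nonexonic SNV with one damaging call and
two missing calls is *not* deleterious (cannot reach two damaging votes),
while a nonsynonymous exonic SNV with the same calls *is* deleterious
(cannot reach two benign votes). The wording is the only signal on missing
behavior, so the asymmetry is retained and surfaced through the
`consensus_rule` column rather than hidden.

## Arm-level copy number

The arm score is the length-weighted mean segment log2 ratio over the arm
(segments clipped to arm bounds). The shipped arm table is the standard
hg19 cytoband-derived set of 39 autosomal arms (acrocentric p arms
excluded); it is a plain DataFrame and can be overridden. Calls are strict:
gain iff score > 0.1, loss iff score < −0.1, so a score of exactly ±0.1 is
neutral; z-score cutoffs are inclusive (≥ 6 arm-level, ≥ 3 focal).

Cohort recurrence uses a within-sample arm-label permutation null: each
sample's vector of arm calls is shuffled across arm labels, preserving
per-sample event burden while destroying arm identity. For each
arm × direction, z = (observed frequency − permutation mean)/permutation
SD, and the permutation p-value uses randomized tie-breaking,
p = (#{perm > obs} + U·(#{perm = obs} + 1))/(n_perm + 1) with U ~ U(0,1),
which is exactly uniform under the exchangeable null despite the heavy
discreteness of event frequencies (the conservative tie-inclusive p-value
is available via `randomize_ties=False`). BH adjustment runs across all
arm × direction tests; significance requires both z ≥ 6 and FDR < 0.05.
Default `n_perm=10_000` (1000 in most tests); fewer than 100 permutations
is rejected as a configuration error. When the permutation SD is zero
(e.g. an event-free cohort) z is defined as 0.

The focal-amplification flag applies the same idea within one sample:
the locus score is compared against scores obtained by redrawing segment
ratios from the sample's own segment pool; flagged at z ≥ 3. Isodisomy is
flagged when the length-weighted median |BAF − 0.5| over the arm exceeds
`baf_dev` (default 0.3 — halfway between the heterozygous deviation 0 and
the homozygous deviation 0.5, robust to noiseless and mildly noisy BAFs)
while the arm score stays in the neutral band, i.e. allelic imbalance that
copy number cannot explain.

This permutation scheme is a desk-scale analog of marker-permutation CNV
significance scanners, chosen to reproduce the published cutoff semantics;
it is not a replication of any specific tool's semi-exact null.

## Peak integration

Replicate intersection clusters all peaks from both sets by transitive
≥ 1 bp overlap (coordinates 0-based half-open) and emits the union span of
every cluster containing members of both replicates; the operation is
symmetric in its arguments. Peak-to-gene assignment links each peak center
to the gene with the minimum |signed distance| to its TSS, unbounded range,
ties broken by lexicographically smallest gene id; the signed distance is
measured TSS → peak center and negated on minus-strand genes so negative
always means upstream. Nearest-TSS with unlimited range is the convention
of the common annotation tools; the published association rule is not
recoverable, so published link counts are not replicated, only the
accounting identities over them. Distance bins on |d|: ≤ 3 kb promoter
(inclusive), (3, 10] kb, (10, 100] kb, > 100 kb. Feature annotation tests
the peak center against promoter (TSS ± 3 kb) and supplied structure
intervals with fixed priority promoter > 5'UTR > 3'UTR > exon > intron >
intergenic. DE integration labels links by their gene's direction at
FDR < 0.05 and reports per-direction gene/peak counts and the bin
distribution, which partition the linked set (property-tested).
Super-enhancer overlap counts SE intervals containing ≥ 1 bp of ≥ 1 peak
and reports the fraction to one decimal percent.

## Motif analysis

Consensus scanning matches IUPAC patterns on both strands at every offset;
a window containing N never matches (N is an unknown base, not a
wildcard). PWM scanning scores log2 odds against the background (default
uniform) and accepts windows at ≥ `score_threshold` × maximum attainable
score, default 0.8 — the common known-motif scanning default. The bundled
motif set (ERRE TNAAGGTCA; CRX/OTX2 TAATCC; NEUROD CAGCTG; LHX TAATTA) is a
compact consensus approximation of public motif-collection entries,
sufficient for end-to-end runs and fixtures; conclusions about real
binding sites require curated matrices supplied by the user.
Co-occurrence uses UpSet semantics: each region counts toward exactly the
subset of motifs present, so subset counts partition the regions.
Enrichment is a one-sided hypergeometric test of presence in a target set
against a background (default: all other rows), BH-adjusted across motifs.
As with the permutation test, a randomized-tie p-value mode exists and is
what calibration studies should use; the default is the standard
conservative tail.

## Single-cell QC

Boundaries follow the stated rules exactly: keep iff total UMI > 400
(strict), 100 ≤ genes detected ≤ 6000 (inclusive both ends) and
mitochondrial fraction < 0.10 (strict). Mitochondrial genes are selected by
symbol prefix `MT-` by default or an explicit list. Summaries normalize to
counts-per-million per cell with log1p; detection is raw count > 0.
Co-detection uses the two-sided Fisher exact test; a diagonal-degenerate
table reports an infinite odds ratio. Clustering, integration, embedding
and doublet detection are out of scope; group labels are inputs.

## Reporting

`percentage` computes 100·count/total with round-half-up at one decimal
using exact integer arithmetic (no binary floating-point boundary
surprises). Oncoprint cells take the highest-priority alteration per
gene × sample (default priority homozygous deletion > stop-gain > splicing
> indel > missense, configurable — a display convention); columns are
ordered by total alteration burden.

## Synthetic generators

The generators define the study conditions for every test. The variant
cohort defaults mirror a ~100-tumor exome cohort with ~90% matched blood
and a panel of 117 normals. Allele fractions are Beta-distributed per
class: somatic Beta(3.5, 6.5) (mean 0.35), heterozygous germline
Beta(40, 40) (tight around 0.5), artifact Beta(0.6, 19.4) (mean 0.03) — the
artifact and somatic means deliberately straddle the 5% VAF cutoff. Read
counts are Binomial(depth, VAF) with Poisson depth (tumor mean 150×, blood
100×), the simplest model that makes read-count filters meaningful.
Germline variants of matched samples reappear in blood reads
(Binomial(depth, 0.5)); half of germline variants are "common"
(population MAF 1–40%, dbSNP-listed). Half of germline variants and 30% of
artifacts are planted in the panel of normals with ≥ 2 carriers; somatic
variants never are. Predictor calls flip the true deleteriousness label
independently per predictor with probability 0.1, report
"possibly damaging" for 30% of damaging PolyPhen-2 calls, and go missing
with probability 0.05.

Arm segments tile each arm with Dirichlet-width segments around the
planted mean log2 ratio plus Gaussian noise (default sd 0.05, roughly the
segment-level scatter of a clean exome-derived profile). The integration
fixture spaces genes 300 kb apart so the planted gene is always the unique
nearest TSS for planted distances ≤ 140 kb, making bin recovery exact at
zero noise. Planted low-quality cells each violate exactly one QC rule by
construction (350 total UMIs, 52 detected genes, or 25% mitochondrial
content).

None of the generators simulate raw reads, alignment artifacts, mutational
signatures, linkage, GC bias or empty droplets. Passing tests therefore
demonstrate that the *rules* are implemented exactly as specified and are
recoverable under the stated generative models — not that the pipeline's
sensitivity/specificity on real tumor data matches any published cohort,
which depends on upstream callers and data quality outside this package's
scope.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale: 100-seed cascade/oracle
comparisons use ~2000-variant cohorts; recurrence calibration uses 50
replicates of 20-sample cohorts at 1000 permutations; interval/scan oracle
sweeps use 200 random fixtures of up to a few hundred intervals. Published
cohort-level results that depend on controlled-access raw data
(per-gene mutation frequencies, absolute peak counts) are not reproduced;
the arithmetic identities over their printed numerators and denominators
are. Degenerate inputs are defined explicitly: empty cohorts return empty
outputs; an arm with no overlapping segments is an error for `arm_score`;
a zero permutation SD yields z = 0; a peak on a chromosome without genes
yields a null link in the far bin.
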